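"""Independent brute-force oracles.

Everything here is written as plainly as possible (dicts, loops, no shared
code with the package) so the package implementations can be checked against
genuinely independent enumerations.
"""

from __future__ import annotations

import numpy as np


def brute_binarize(x):
    """Circular rise/fall bits by direct rule application."""
    bits = []
    for n in range(len(x)):
        prev = x[n - 1]  # python negative indexing gives the circular seam
        bits.append(1 if x[n] > prev else 0)
    return bits


def brute_word_counts(bits, m):
    """Counts of all circular m-bit windows, MSB first, via string parsing."""
    L = len(bits)
    counts = {}
    for n in range(L):
        window = "".join(str(bits[(n + j) % L]) for j in range(m))
        w = int(window, 2)
        counts[w] = counts.get(w, 0) + 1
    return counts


def brute_ranks(counts, m):
    """Rank 1 = most frequent; count ties broken by ascending word value."""
    items = [(w, counts.get(w, 0)) for w in range(2**m)]
    items.sort(key=lambda t: (-t[1], t[0]))
    ranks = {}
    for pos, (w, _) in enumerate(items, start=1):
        ranks[w] = pos
    return ranks


def brute_probs(counts, m):
    total = sum(counts.values())
    return {w: counts.get(w, 0) / total for w in range(2**m)}


def brute_dm(counts1, counts2, m):
    """Direct evaluation of the normalized rank-difference dissimilarity."""
    p1 = brute_probs(counts1, m)
    p2 = brute_probs(counts2, m)
    r1 = brute_ranks(counts1, m)
    r2 = brute_ranks(counts2, m)
    denom_sum = sum(p1[w] * p2[w] for w in range(2**m))
    if denom_sum == 0:
        return 1.0
    num = sum(abs(r1[w] - r2[w]) * p1[w] * p2[w] for w in range(2**m))
    return num / ((2**m - 1) * denom_sum)


def brute_rank_diff_sum(counts1, counts2, m):
    p1 = brute_probs(counts1, m)
    p2 = brute_probs(counts2, m)
    r1 = brute_ranks(counts1, m)
    r2 = brute_ranks(counts2, m)
    return sum(
        abs(r1[w] - r2[w]) for w in range(2**m) if p1[w] + p2[w] > 0
    )


def brute_percent_sym(values, k):
    L = len(values)
    num = 0.0
    den = 0.0
    for i in range(L):
        a = values[i]
        b = values[(2 * k - i) % L]
        num += abs(a - b)
        den += 2.0 * (a * b) ** 0.5
    return 1.0 - num / den


def brute_spiral_cells(h, w, start=None):
    """Spiral visiting order by explicit direction bookkeeping.

    Directions cycle +row, +col, -row, -col with run lengths 1, 1, 2, 2, ...;
    out-of-grid cells are skipped until every grid cell has been visited.
    """
    if start is None:
        start = ((h - 1) // 2, (w - 1) // 2)
    r, c = start
    cells = []
    if 0 <= r < h and 0 <= c < w:
        cells.append((r, c))
    directions = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    run_len = 1
    d = 0
    guard = 0
    while len(cells) < h * w:
        for _ in range(run_len):
            r += directions[d][0]
            c += directions[d][1]
            if 0 <= r < h and 0 <= c < w:
                cells.append((r, c))
        d = (d + 1) % 4
        if d in (0, 2):  # run length grows after -row and after +row turns
            run_len += 1
        guard += 1
        if guard > 100 * (h + w) ** 2:
            raise RuntimeError("spiral oracle did not terminate")
    return cells


def brute_spiral_walk_in_mask(image, mask, start):
    """Gray values along the spiral until the first in-grid cell off the mask."""
    h, w = mask.shape
    r0, c0 = start
    values = []
    directions = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    r, c = r0, c0
    if not mask[r, c]:
        raise ValueError("start off mask")
    values.append(float(image[r, c]))
    run_len = 1
    d = 0
    seen = 1
    while True:
        for _ in range(run_len):
            r += directions[d][0]
            c += directions[d][1]
            if not (0 <= r < h and 0 <= c < w):
                continue
            if not mask[r, c]:
                return values
            values.append(float(image[r, c]))
            seen += 1
            if seen == h * w:
                return values
        d = (d + 1) % 4
        if d in (0, 2):
            run_len += 1


def brute_boundary_pixels(mask):
    """Mask pixels with at least one 4-connected background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    out = set()
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            pr, pc = r + 1, c + 1
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                if not padded[pr + dr, pc + dc]:
                    out.add((r, c))
                    break
    return out


def draw_ellipse_mask(shape, center, a, b, angle=0.0):
    """Independent ellipse rasterizer: inside iff (u/a)^2 + (v/b)^2 <= 1."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rows - center[0]
    dx = cols - center[1]
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def brute_dividing_line(values, labels, direction="below"):
    """Best-threshold search over a dense candidate set."""
    values = list(map(float, values))
    normal = [lab == "normal" for lab in labels]
    uniq = sorted(set(values))
    cands = [uniq[0]] + [
        (lo + hi) / 2 for lo, hi in zip(uniq[:-1], uniq[1:])
    ] + [uniq[-1] + 1.0]
    best = None
    for dl in cands:
        if direction == "below":
            pred = [v < dl for v in values]
        else:
            pred = [v > dl for v in values]
        acc = sum(p == t for p, t in zip(pred, normal)) / len(values)
        if best is None or acc > best[1]:
            best = (dl, acc)
    return best
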