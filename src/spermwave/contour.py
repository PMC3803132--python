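"""Contour tracing and the two 1-D waveform descriptors of a head boundary.

The boundary is traced with the Moore neighbourhood algorithm (clockwise in
image coordinates, starting at the top-most then left-most boundary pixel).
Two circular waveforms are derived from the closed contour:

* the centroid-distance waveform: one centroid-to-boundary distance per
  contour point, invariant to translation and (as a circular sequence)
  covariant with rotation and scale;
* the symmetry-pair waveform: Euclidean distances between contour points
  paired across the best bilateral symmetry axis; its values depend on the
  chosen anchor, which is exactly the start-point sensitivity that motivates
  the rank encoding downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .errors import ContourError

__all__ = [
    "Contour",
    "Centroid",
    "Waveform",
    "trace_contour",
    "centroid",
    "distance_waveform",
    "symmetry_scores",
    "percent_sym",
    "symmetry_waveform",
]

# clockwise Moore neighbourhood in image coordinates (row down):
# W, NW, N, NE, E, SE, S, SW
_NEIGHBOURS = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class Contour:
    """Ordered closed boundary of one head; first point adjacent to last."""

    points: np.ndarray  # (L, 2) int array of (row, col)
    orientation: str = "clockwise"

    def __post_init__(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (L, 2) array")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Centroid:
    """Arithmetic mean of the contour points (x = column, y = row)."""

    x_mid: float
    y_mid: float


@dataclass(frozen=True)
class Waveform:
    """A circular 1-D descriptor derived from a contour."""

    values: np.ndarray
    source: str  # "centroid-distance" or "symmetry"
    circular: bool = True

    def __len__(self) -> int:
        return len(self.values)


def trace_contour(mask: np.ndarray) -> Contour:
    """Moore boundary trace of a single-component mask.

    Starts at the top-most then left-most boundary pixel and walks clockwise
    in image coordinates.  Raises :class:`ContourError` for empty, degenerate
    (< 8 boundary pixels) or multi-component masks.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ContourError("empty mask")
    _, n = cc_label(mask, connectivity=2, return_num=True)
    if n != 1:
        raise ContourError(f"mask has {n} components, expected exactly 1")

    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # row-major nonzero: topmost, then leftmost

    points = [start]
    # backtrack: the background pixel we "came from"; W of start is background
    current = start
    backtrack = (start[0], start[1] - 1)
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    max_steps = 4 * int(mask.sum()) + 16
    for _ in range(max_steps):
        # index of backtrack among current's neighbours
        db = (backtrack[0] - current[0], backtrack[1] - current[1])
        bi = _NEIGHBOURS.index(db)
        nxt = None
        for j in range(1, 9):
            dr, dc = _NEIGHBOURS[(bi + j) % 8]
            cand = (current[0] + dr, current[1] + dc)
            if padded[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel
            break
        if first_move is None:
            first_move = (current, nxt)
        elif (current, nxt) == first_move:
            points.pop()  # the start point was re-appended before detecting closure
            break
        points.append(nxt)
        current = nxt
    else:
        raise ContourError("boundary trace did not close")

    pts = np.array(points, dtype=int) - 1  # undo padding offset
    if len(pts) < 8:
        raise ContourError(f"contour has {len(pts)} points, need >= 8")
    return Contour(points=pts)


def centroid(contour: Contour) -> Centroid:
    """Mean of the contour points themselves (not of interior pixels)."""
    pts = contour.points
    return Centroid(x_mid=float(pts[:, 1].mean()), y_mid=float(pts[:, 0].mean()))


def distance_waveform(contour: Contour, c: Centroid | None = None) -> Waveform:
    """Centroid-to-boundary distance, one value per contour point."""
    if c is None:
        c = centroid(contour)
    pts = contour.points
    d = np.hypot(pts[:, 1] - c.x_mid, pts[:, 0] - c.y_mid)
    return Waveform(values=d, source="centroid-distance")


def symmetry_scores(contour: Contour) -> np.ndarray:
    """Bilateral symmetry score of each candidate axis anchor.

    The candidate axis through anchor ``n`` runs from contour point ``n``
    through the centroid.  Points ``n+i`` and ``n-i`` (circularly) are the
    candidate mirror pairs; the score is the summed squared distance between
    point ``n+i`` and the reflection of point ``n-i`` across the axis.  Lower
    means more symmetric.
    """
    pts = contour.points.astype(float)
    L = len(pts)
    if L < 8:
        raise ContourError("contour too short for symmetry scoring")
    c = centroid(contour)
    centre = np.array([c.y_mid, c.x_mid])
    rel = pts - centre  # (L, 2) in (row, col)
    half = (L - 1) // 2
    scores = np.empty(L)
    for n in range(L):
        axis = rel[n]
        norm = np.hypot(*axis)
        if norm == 0:
            scores[n] = np.inf
            continue
        u = axis / norm
        idx_fwd = (n + np.arange(1, half + 1)) % L
        idx_bwd = (n - np.arange(1, half + 1)) % L
        q = rel[idx_bwd]
        # reflection across the line through the centroid with direction u
        proj = q @ u
        mirrored = 2 * proj[:, None] * u[None, :] - q
        diff = rel[idx_fwd] - mirrored
        scores[n] = float((diff**2).sum())
    return scores


def percent_sym(waveform: Waveform | np.ndarray, k: int) -> float:
    """Symmetry percentage of a circular waveform about index ``k``.

    ``1 - sum |A(i) - A(2k-i)| / sum 2*sqrt(A(i)*A(2k-i))`` with indices taken
    modulo the length; equals 1 exactly when the waveform is symmetric about
    ``k``.  A zero-valued pair makes the normalization degenerate and raises
    ``ZeroDivisionError``.
    """
    values = waveform.values if isinstance(waveform, Waveform) else np.asarray(waveform, float)
    L = len(values)
    if L < 2:
        raise ValueError("waveform must have at least 2 values")
    i = np.arange(L)
    paired = values[(2 * k - i) % L]
    products = values * paired
    if np.any(products == 0):
        raise ZeroDivisionError("zero-valued pair in percent_sym normalization")
    num = np.abs(values - paired).sum()
    den = (2.0 * np.sqrt(products)).sum()
    return float(1.0 - num / den)


def best_symmetry_anchor(contour: Contour) -> int:
    """Global argmin of the symmetry scores; ties break to the lowest index."""
    return int(np.argmin(symmetry_scores(contour)))


def symmetry_waveform(contour: Contour, k: int | None = None) -> Waveform:
    """Distances between contour points paired across the axis anchored at ``k``.

    Value ``j`` is the Euclidean distance between points ``k+j`` and ``k-j``
    (circularly) for ``j = 0 .. L//2``.  When ``k`` is omitted the best
    symmetry anchor is used; passing an explicit ``k`` exposes the start-point
    sensitivity of this descriptor.
    """
    if k is None:
        k = best_symmetry_anchor(contour)
    pts = contour.points.astype(float)
    L = len(pts)
    j = np.arange(L // 2 + 1)
    p = pts[(k + j) % L]
    q = pts[(k - j) % L]
    d = np.hypot(*(p - q).T)
    return Waveform(values=d, source="symmetry")
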