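"""Gray-level features: darkness statistics and the square-spiral scan.

The spiral ("roundabout") path starts at a centre cell, first steps toward
larger row indices, then turns toward larger column indices, with run lengths
1, 1, 2, 2, 3, 3, ...  Cells falling outside the grid are skipped (the walk
continues); gray extraction along a head additionally terminates at the first
cell that leaves the head mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .segment import SpermCrop

__all__ = [
    "GrayStats",
    "SpiralPath",
    "gray_stats",
    "spiral_path",
    "spiral_index_grid",
    "spiral_gray_sequence",
]


@dataclass(frozen=True)
class GrayStats:
    """Summed gray level G over n in-mask pixels and darkness fraction P."""

    G: int
    n: int
    P: float


def gray_stats(crop: SpermCrop) -> GrayStats:
    """Gray sum and darkness percentage over the in-mask pixels.

    ``P = 1 - G / (255 n)``: 1 for an all-black head, 0 for an all-white one.
    """
    pixels = np.asarray(crop.image)[crop.mask]
    if pixels.size == 0:
        raise ValueError("mask must be non-empty")
    G = int(pixels.sum(dtype=np.int64))
    n = int(pixels.size)
    return GrayStats(G=G, n=n, P=1.0 - G / (255.0 * n))


def _spiral_offsets() -> Iterator[tuple[int, int]]:
    """Infinite square spiral offsets: (0,0), then +row, +col, -row, -col runs."""
    yield (0, 0)
    r = c = 0
    run = 1
    while True:
        for dr, dc, steps in ((1, 0, run), (0, 1, run), (-1, 0, run + 1), (0, -1, run + 1)):
            for _ in range(steps):
                r += dr
                c += dc
                yield (r, c)
        run += 2


@dataclass(frozen=True)
class SpiralPath:
    """Ordered spiral offsets relative to the start cell; index 1 at (0, 0)."""

    offsets: tuple[tuple[int, int], ...]
    extent: tuple[int, int]
    start: tuple[int, int]


def default_start(extent: tuple[int, int]) -> tuple[int, int]:
    """Centre cell of a grid: row 4, col 4 (1-based) for an 8x8 extent."""
    return ((extent[0] - 1) // 2, (extent[1] - 1) // 2)


def spiral_path(extent: tuple[int, int], start: tuple[int, int] | None = None) -> SpiralPath:
    """Spiral visiting order of every cell of an ``extent`` grid.

    Offsets are relative to the start cell; out-of-grid cells are skipped and
    the walk continues until all ``rows * cols`` cells are covered.
    """
    h, w = extent
    if h < 1 or w < 1:
        raise ValueError("extent must be at least 1x1")
    if start is None:
        start = default_start(extent)
    r0, c0 = start
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("start cell must lie inside the grid")
    offsets: list[tuple[int, int]] = []
    for dr, dc in _spiral_offsets():
        r, c = r0 + dr, c0 + dc
        if 0 <= r < h and 0 <= c < w:
            offsets.append((dr, dc))
            if len(offsets) == h * w:
                break
    return SpiralPath(offsets=tuple(offsets), extent=(h, w), start=(r0, c0))


def spiral_index_grid(extent: tuple[int, int], start: tuple[int, int] | None = None) -> np.ndarray:
    """Grid of 1-based visit indices of the spiral walk over ``extent``."""
    path = spiral_path(extent, start)
    grid = np.zeros(path.extent, dtype=int)
    r0, c0 = path.start
    for i, (dr, dc) in enumerate(path.offsets, start=1):
        grid[r0 + dr, c0 + dc] = i
    return grid


def spiral_gray_sequence(
    crop: SpermCrop, start: tuple[int, int] | str = "mask-centroid"
) -> np.ndarray:
    """Gray values along the spiral from the head centre until mask exit.

    The walk skips cells outside the crop grid and stops at the first in-grid
    cell outside the mask (the path "collides with the contour").  The start
    is the rounded mask centroid unless explicit crop coordinates are given;
    it must lie inside the mask.
    """
    image = np.asarray(crop.image)
    mask = np.asarray(crop.mask, dtype=bool)
    h, w = mask.shape
    if isinstance(start, str):
        if start != "mask-centroid":
            raise ValueError(f"unknown start mode {start!r}")
        rr, cc = np.nonzero(mask)
        start_cell = (int(np.round(rr.mean())), int(np.round(cc.mean())))
    else:
        start_cell = (int(start[0]), int(start[1]))
    r0, c0 = start_cell
    if not (0 <= r0 < h and 0 <= c0 < w) or not mask[r0, c0]:
        raise ValueError(f"start cell {start_cell} lies outside the mask")

    values: list[float] = []
    seen = 0
    total = h * w
    for dr, dc in _spiral_offsets():
        r, c = r0 + dr, c0 + dc
        if not (0 <= r < h and 0 <= c < w):
            continue
        if not mask[r, c]:
            break
        values.append(float(image[r, c]))
        seen += 1
        if seen == total:  # mask fills the whole grid
            break
    return np.asarray(values)
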