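"""Micrograph segmentation: gray thresholding, components, tail removal, crops.

All coordinates are 0-based ``(row, col)`` with row 0 at the top.  Bounding
boxes are half-open ``(r0, c0, r1, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, opening

from .errors import DegenerateComponentError

__all__ = [
    "SpermCrop",
    "threshold_segment",
    "extract_components",
    "remove_tail",
    "crop_head",
]

Box = tuple[int, int, int, int]


@dataclass
class SpermCrop:
    """A head-only crop of the source image with its aligned mask.

    ``origin`` is the (row, col) offset of the crop in the source image.
    Pixels outside the mask are retained in ``image``; gray statistics are
    restricted by ``mask``.
    """

    image: np.ndarray
    mask: np.ndarray
    origin: tuple[int, int]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not self.mask.any():
            raise ValueError("mask must be non-empty")


def threshold_segment(
    image: np.ndarray,
    roi: list[Box] | None = None,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Mark pixels darker than ``threshold`` inside the ROI boxes.

    ``roi=None`` means the whole image; an explicitly empty ROI list is an
    error.  ``threshold="otsu"`` picks Otsu's threshold from the ROI pixels.
    """
    image = np.asarray(image)
    if roi is not None and len(roi) == 0:
        raise ValueError("ROI list must not be empty (pass None for whole image)")
    region = np.zeros(image.shape, dtype=bool)
    if roi is None:
        region[:] = True
    else:
        for r0, c0, r1, c1 in roi:
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"degenerate ROI box {(r0, c0, r1, c1)}")
            region[r0:r1, c0:c1] = True
    pixels = image[region]
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if pixels.min() == pixels.max():
            return np.zeros(image.shape, dtype=bool)
        thr = threshold_otsu(pixels)
    else:
        if not 0 <= threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        thr = threshold
    # darker-than-threshold; <= matches Otsu's foreground/background split
    # convention for dark objects (the threshold value belongs to the dark side)
    return (image <= thr) & region


def extract_components(
    mask: np.ndarray, min_area: int = 1
) -> list[tuple[np.ndarray, Box]]:
    """Split a mask into 8-connected components of area >= ``min_area``.

    Returns ``(component crop, bbox)`` pairs sorted by the bounding box
    top-left corner in row-major order.  Each crop contains exactly one
    component and is aligned to its bbox.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    labeled, n = cc_label(np.asarray(mask, dtype=bool), connectivity=2, return_num=True)
    out: list[tuple[np.ndarray, Box]] = []
    for i in range(1, n + 1):
        comp = labeled == i
        if comp.sum() < min_area:
            continue
        rows = np.flatnonzero(comp.any(axis=1))
        cols = np.flatnonzero(comp.any(axis=0))
        bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        out.append((comp[bbox[0] : bbox[2], bbox[1] : bbox[3]], bbox))
    out.sort(key=lambda item: (item[1][0], item[1][1]))
    return out


def remove_tail(component: np.ndarray, width_threshold: int = 4) -> np.ndarray:
    """Strip thin appendages (tails) from a connected component mask.

    Morphological opening with a disc of radius ``width_threshold`` removes
    structures locally thinner than the disc; the largest surviving component
    is kept and re-dilated within the original mask to recover boundary
    pixels eroded by the opening.
    """
    component = np.asarray(component, dtype=bool)
    selem = disk(width_threshold)
    pad = width_threshold + 1
    padded = np.pad(component, pad)
    opened = opening(padded, selem)
    if not opened.any():
        raise DegenerateComponentError(
            f"opening with disc radius {width_threshold} erased the component"
        )
    labeled, n = cc_label(opened, connectivity=2, return_num=True)
    if n > 1:
        areas = np.bincount(labeled.ravel())[1:]
        opened = labeled == (int(np.argmax(areas)) + 1)
    head = dilation(opened, selem) & padded
    # a curved tail can loop back into the dilation ring as a detached piece
    labeled, n = cc_label(head, connectivity=2, return_num=True)
    if n > 1:
        areas = np.bincount(labeled.ravel())[1:]
        head = labeled == (int(np.argmax(areas)) + 1)
    return head[pad:-pad, pad:-pad]


def crop_head(
    image: np.ndarray,
    mask: np.ndarray,
    origin: tuple[int, int] = (0, 0),
    margin: int = 2,
    label: str | None = None,
) -> SpermCrop:
    """Cut the mask's bounding box (plus margin) out of the source image.

    ``mask`` may be a full-frame mask (``origin=(0, 0)``) or a crop whose
    top-left corner sits at ``origin`` in ``image``.  The margin is clipped at
    the image border; the recorded origin refers to the source image.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(origin[0] + int(rows[0]) - margin, 0)
    c0 = max(origin[1] + int(cols[0]) - margin, 0)
    r1 = min(origin[0] + int(rows[-1]) + 1 + margin, image.shape[0])
    c1 = min(origin[1] + int(cols[-1]) + 1 + margin, image.shape[1])
    full_mask = np.zeros(image.shape, dtype=bool)
    full_mask[origin[0] : origin[0] + mask.shape[0], origin[1] : origin[1] + mask.shape[1]] = mask
    return SpermCrop(
        image=image[r0:r1, c0:c1].copy(),
        mask=full_mask[r0:r1, c0:c1],
        origin=(r0, c0),
        label=label,
    )
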