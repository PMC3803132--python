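"""Synthetic micrograph generation with per-sperm ground truth.

Scenes mimic the structure the downstream stages assume: a uniform bright
background with additive sensor noise, darker elliptical heads (normal heads
are smooth mid-dark ovals; abnormal heads are too round, too slim, rough-edged,
or abnormally pale/dark) and thin curved tails attached to the heads.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PlacementError, SizeError

__all__ = [
    "HeadParams",
    "MaskPatch",
    "SceneConfig",
    "SyntheticScene",
    "generate_head",
    "generate_scene",
    "write_scene",
]

#: number of low-order harmonics used for the boundary perturbation
_ROUGH_HARMONICS = (2, 3, 4, 5)


@dataclass(frozen=True)
class HeadParams:
    """Parameters of one synthetic sperm head.

    ``orientation`` is the angle of the major axis measured from the +column
    axis toward the +row axis, in radians.  ``boundary_roughness`` is the
    amplitude of a low-order periodic perturbation of the ellipse radius, as a
    fraction of the local radius; it must stay below 0.5 so the boundary
    remains a single closed curve.
    """

    semi_major: float
    semi_minor: float
    boundary_roughness: float = 0.0
    mean_intensity: float = 115.0
    intensity_noise_sd: float = 4.0
    orientation: float = 0.0
    tail_length: float = 0.0
    gradient_amp: float = 40.0

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("require semi_major >= semi_minor > 0")
        if not 0.0 <= self.boundary_roughness < 0.5:
            raise ValueError("boundary_roughness must lie in [0, 0.5)")
        if not 0.0 <= self.mean_intensity <= 255.0:
            raise ValueError("mean_intensity must lie in [0, 255]")
        if self.intensity_noise_sd < 0 or self.tail_length < 0:
            raise ValueError("noise sd and tail length must be non-negative")

    @property
    def axis_ratio(self) -> float:
        return self.semi_major / self.semi_minor

    def reach(self) -> float:
        """Worst-case radius from the head centre covered by head plus tail."""
        return self.semi_major * (1.0 + self.boundary_roughness) + self.tail_length + 3.0


@dataclass(frozen=True)
class MaskPatch:
    """A binary mask crop positioned at ``origin`` (row, col) in a larger frame."""

    origin: tuple[int, int]
    mask: np.ndarray

    def to_full(self, shape: tuple[int, int]) -> np.ndarray:
        full = np.zeros(shape, dtype=bool)
        r, c = self.origin
        h, w = self.mask.shape
        full[r : r + h, c : c + w] = self.mask
        return full

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _boundary_radius(params: HeadParams, theta: np.ndarray, rng: np.random.Generator):
    """Radius of the (possibly rough) ellipse boundary at polar angle theta.

    Returns ``(radius_fn_values, harmonics)`` where harmonics are drawn from
    ``rng`` exactly once so the mask is reproducible independently of any
    later draws (tail shape, intensity noise).
    """
    a, b = params.semi_major, params.semi_minor
    base = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    amps = rng.uniform(0.4, 1.0, size=len(_ROUGH_HARMONICS))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(_ROUGH_HARMONICS))
    if params.boundary_roughness == 0.0:
        return base, (amps, phases)
    fine = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    norm = np.abs(_harmonic(fine, amps, phases)).max()
    perturb = _harmonic(theta, amps, phases) / norm
    return base * (1.0 + params.boundary_roughness * perturb), (amps, phases)


def _harmonic(theta: np.ndarray, amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    out = np.zeros_like(theta, dtype=float)
    for h, amp, ph in zip(_ROUGH_HARMONICS, amps, phases):
        out = out + amp * np.cos(h * theta + ph)
    return out


def generate_head(
    params: HeadParams,
    canvas: tuple[int, int],
    seed: int,
    *,
    center: tuple[float, float] | None = None,
    background: float = 230.0,
    background_noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one sperm (head plus optional tail) on a bright canvas.

    Returns ``(image, mask)``: an 8-bit grayscale image and the boolean sperm
    mask (head and tail).  Rendering is bit-deterministic in ``(params, seed)``.
    The same seed with ``tail_length=0`` reproduces the identical head-only
    mask, which is how scenes obtain ground-truth head masks.
    """
    if params.mean_intensity >= background:
        raise ValueError("head mean_intensity must be below the background intensity")
    h, w = canvas
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    r0, c0 = center
    margin = min(r0, c0, h - 1 - r0, w - 1 - c0)
    if params.reach() > margin:
        raise SizeError(
            f"head reach {params.reach():.1f}px exceeds canvas margin {margin:.1f}px"
        )
    rng = np.random.default_rng(seed)

    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - r0
    dx = cols - c0
    phi = params.orientation
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    radius, (amps, phases) = _boundary_radius(params, theta.ravel(), rng)
    radius = radius.reshape(theta.shape)
    head = rho <= radius

    # tail: a curved 2-3 px stroke leaving the major-axis tip
    tail = np.zeros_like(head)
    bend = rng.uniform(-0.25, 0.25)
    bend_phase = rng.uniform(0.0, np.pi)
    if params.tail_length > 0:
        a_eff = params.semi_major
        # anchor deep enough that a rough boundary cannot detach the tail
        anchor = params.boundary_roughness * params.semi_major + 2.0
        n_samp = max(int(params.tail_length * 2), 4)
        s = np.linspace(-anchor, params.tail_length, n_samp)
        lateral = params.tail_length * bend * np.sin(np.pi * s / params.tail_length + bend_phase) * (
            np.clip(s, 0, None) / params.tail_length
        )
        px = c0 + (a_eff + s) * np.cos(phi) - lateral * np.sin(phi)
        py = r0 + (a_eff + s) * np.sin(phi) + lateral * np.cos(phi)
        px = np.clip(px, 1, w - 2)
        py = np.clip(py, 1, h - 2)
        half_width = 1.25
        rmin = max(int(py.min() - 3), 0)
        rmax = min(int(py.max() + 4), h)
        cmin = max(int(px.min() - 3), 0)
        cmax = min(int(px.max() + 4), w)
        sub_r, sub_c = np.mgrid[rmin:rmax, cmin:cmax]
        d2 = np.full(sub_r.shape, np.inf)
        for x, y in zip(px, py):
            d2 = np.minimum(d2, (sub_r - y) ** 2 + (sub_c - x) ** 2)
        tail[rmin:rmax, cmin:cmax] = d2 <= half_width**2

    mask = head | tail

    image = np.full((h, w), float(background))
    if background_noise_sd > 0:
        image += rng.normal(0.0, background_noise_sd, size=(h, w))
    rho_norm = np.clip(np.divide(rho, radius, out=np.ones_like(rho), where=radius > 0), 0, 1)
    shade = params.mean_intensity + params.gradient_amp * (rho_norm**2 - 0.5)
    if params.intensity_noise_sd > 0:
        shade = shade + rng.normal(0.0, params.intensity_noise_sd, size=(h, w))
    image[head] = shade[head]
    tail_only = tail & ~head
    image[tail_only] = np.clip(shade[tail_only] + 25.0, 0, 255)
    return np.clip(image, 0, 255).astype(np.uint8), mask


# ---------------------------------------------------------------------------
# scene generation


@dataclass(frozen=True)
class SceneConfig:
    """Distribution spec for synthetic scenes.

    The intensity ranges are free parameters (no published statistics exist
    for the original micrographs); defaults give a mid-dark normal class,
    clearly pale/dark intensity-anomaly heads, and shape anomalies whose axis
    ratios sit outside the 1.2-1.8 ovality band.
    """

    background: float = 230.0
    background_noise_sd: float = 1.0
    cell_pad: int = 8
    jitter: int = 3
    image_shape: tuple[int, int] | None = None

    normal_minor: tuple[float, float] = (12.0, 15.0)
    normal_ratio: tuple[float, float] = (1.25, 1.75)
    normal_roughness: tuple[float, float] = (0.0, 0.04)
    normal_intensity: tuple[float, float] = (100.0, 130.0)
    normal_gradient: tuple[float, float] = (80.0, 120.0)
    intensity_noise_sd: float = 1.0
    tail_length: tuple[float, float] = (16.0, 26.0)

    round_ratio: tuple[float, float] = (1.0, 1.12)
    slim_ratio: tuple[float, float] = (1.92, 2.2)
    rough_roughness: tuple[float, float] = (0.28, 0.40)
    pale_intensity: tuple[float, float] = (135.0, 160.0)
    dark_intensity: tuple[float, float] = (35.0, 65.0)
    # abnormal chromatin structure: intensity-anomaly heads are washed out,
    # shape-anomaly heads get a weaker condensation gradient than normal
    anomaly_gradient: tuple[float, float] = (0.0, 6.0)
    shape_gradient: tuple[float, float] = (0.0, 6.0)

    def max_reach(self) -> float:
        a = self.normal_minor[1] * max(self.normal_ratio[1], self.slim_ratio[1])
        return a * (1.0 + self.rough_roughness[1]) + self.tail_length[1] + 3.0


_ABNORMAL_KINDS = ("round", "slim", "rough", "intensity")


def _draw_params(rng: np.random.Generator, cfg: SceneConfig, label: str, index: int) -> HeadParams:
    minor = rng.uniform(*cfg.normal_minor)
    ratio = rng.uniform(*cfg.normal_ratio)
    roughness = rng.uniform(*cfg.normal_roughness)
    intensity = rng.uniform(*cfg.normal_intensity)
    gradient = rng.uniform(*cfg.normal_gradient)
    if label == "abnormal":
        kind = _ABNORMAL_KINDS[index % len(_ABNORMAL_KINDS)]
        if kind == "round":
            ratio = rng.uniform(*cfg.round_ratio)
            gradient = rng.uniform(*cfg.shape_gradient)
        elif kind == "slim":
            ratio = rng.uniform(*cfg.slim_ratio)
            gradient = rng.uniform(*cfg.shape_gradient)
        elif kind == "rough":
            roughness = rng.uniform(*cfg.rough_roughness)
            gradient = rng.uniform(*cfg.shape_gradient)
        else:
            band = cfg.pale_intensity if index % 8 < 4 else cfg.dark_intensity
            intensity = rng.uniform(*band)
            gradient = rng.uniform(*cfg.anomaly_gradient)
    return HeadParams(
        semi_major=minor * ratio,
        semi_minor=minor,
        boundary_roughness=roughness,
        mean_intensity=intensity,
        intensity_noise_sd=cfg.intensity_noise_sd,
        orientation=rng.uniform(0.0, np.pi),
        tail_length=rng.uniform(*cfg.tail_length),
        gradient_amp=gradient,
    )


@dataclass
class SyntheticScene:
    """A rendered micrograph plus per-sperm ground truth."""

    image: np.ndarray
    masks: list[MaskPatch]
    head_masks: list[MaskPatch]
    labels: list[str]
    params: list[HeadParams]
    seed: int
    label_image: np.ndarray = field(repr=False, default=None)
    background: float = 230.0

    def __post_init__(self) -> None:
        if not (len(self.masks) == len(self.labels) == len(self.params)):
            raise ValueError("masks, labels and params must be aligned")


def generate_scene(
    n_normal: int,
    n_abnormal: int,
    seed: int,
    config: SceneConfig | None = None,
) -> SyntheticScene:
    """Render a scene with ``n_normal + n_abnormal`` non-overlapping sperms.

    Heads are laid out on a shuffled grid of cells (one sperm per cell, with a
    small positional jitter), which guarantees pairwise-disjoint masks.  If a
    fixed ``config.image_shape`` cannot hold all requested sperms a
    :class:`~spermwave.errors.PlacementError` is raised.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be non-negative")
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    n = n_normal + n_abnormal

    cell = int(np.ceil(2 * cfg.max_reach())) + cfg.cell_pad + 2 * cfg.jitter
    if cfg.image_shape is not None:
        shape = cfg.image_shape
        grid_r, grid_c = shape[0] // cell, shape[1] // cell
        if grid_r * grid_c < n:
            raise PlacementError(
                f"{n} sperms do not fit a {shape[0]}x{shape[1]} image "
                f"({grid_r * grid_c} cells of {cell}px)"
            )
    else:
        side = max(int(np.ceil(np.sqrt(n))), 1)
        grid_r = grid_c = side
        shape = (side * cell, side * cell)

    image = np.clip(
        np.full(shape, cfg.background)
        + (rng.normal(0.0, cfg.background_noise_sd, size=shape) if cfg.background_noise_sd > 0 else 0.0),
        0,
        255,
    ).astype(np.uint8)
    label_image = np.zeros(shape, dtype=np.int32)

    cells = [(r, c) for r in range(grid_r) for c in range(grid_c)]
    rng.shuffle(cells)

    labels = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    masks: list[MaskPatch] = []
    head_masks: list[MaskPatch] = []
    params_list: list[HeadParams] = []
    for i, label in enumerate(labels):
        params = _draw_params(rng, cfg, label, i)
        head_seed = int(rng.integers(0, 2**31 - 1))
        jr = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
        jc = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
        local_img, local_mask = generate_head(
            params, (cell, cell), head_seed, background=cfg.background
        )
        _, local_head = generate_head(
            dataclasses.replace(params, tail_length=0.0),
            (cell, cell),
            head_seed,
            background=cfg.background,
        )
        gr, gc = cells[i]
        r0 = gr * cell + jr if gr * cell + jr >= 0 else 0
        c0 = gc * cell + jc if gc * cell + jc >= 0 else 0
        r0 = min(r0, shape[0] - cell)
        c0 = min(c0, shape[1] - cell)
        region = (slice(r0, r0 + cell), slice(c0, c0 + cell))
        image[region][local_mask] = local_img[local_mask]
        label_image[region][local_mask] = i + 1
        masks.append(_tight_patch(local_mask, (r0, c0)))
        head_masks.append(_tight_patch(local_head, (r0, c0)))
        params_list.append(params)

    return SyntheticScene(
        image=image,
        masks=masks,
        head_masks=head_masks,
        labels=labels,
        params=params_list,
        seed=seed,
        label_image=label_image,
        background=cfg.background,
    )


def _tight_patch(mask: np.ndarray, origin: tuple[int, int]) -> MaskPatch:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return MaskPatch(
        origin=(origin[0] + int(r0), origin[1] + int(c0)),
        mask=mask[r0:r1, c0:c1].copy(),
    )


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> Path:
    """Write ``image.png``, per-sperm mask PNGs and a CSV manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_path = out / "image.png"
    iio.imwrite(image_path, scene.image)
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "sperm_id", "label", "seed", "mask_path"])
        for i, (patch, label) in enumerate(zip(scene.masks, scene.labels)):
            mask_path = mask_dir / f"sperm_{i:03d}.png"
            iio.imwrite(mask_path, patch.to_full(scene.image.shape).astype(np.uint8) * 255)
            writer.writerow(
                [image_path.name, i, label, scene.seed, f"masks/sperm_{i:03d}.png"]
            )
    return manifest
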