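"""Run configuration: YAML loading, validation, defaults.

Defaults follow the published settings wherever one exists: window widths
m=5 (contour) and m=8 (gray spiral), alpha grid 0.1-0.9 in steps of 0.1,
C-SVC/RBF with cost 1, eps 0.001, cache 40 MB, shrinking on, gamma 1/k,
ovality band 1.2-1.8 and k=10 neighbours with the >3 normal cut.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .fixtures import SceneConfig

__all__ = ["RunConfig", "load_config"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixturesConfig(_Model):
    """Synthetic-scene distribution knobs (free parameters; see fixtures)."""

    background: float = 230.0
    background_noise_sd: float = 1.0
    image_shape: Optional[tuple[int, int]] = None
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
    anomaly_gradient: tuple[float, float] = (0.0, 6.0)
    shape_gradient: tuple[float, float] = (0.0, 6.0)

    def to_scene_config(self) -> SceneConfig:
        return SceneConfig(**self.model_dump())


class SimulateConfig(_Model):
    n_normal: int = Field(80, ge=0)
    n_abnormal: int = Field(80, ge=0)
    fixtures: FixturesConfig = FixturesConfig()


class InputConfig(_Model):
    mode: Literal["simulate", "images"] = "simulate"
    images_dir: Optional[str] = None
    manifest: Optional[str] = None
    roi: Optional[list[tuple[int, int, int, int]]] = None
    simulate: SimulateConfig = SimulateConfig()


class SegmentationConfig(_Model):
    threshold: int | Literal["otsu"] = "otsu"
    min_area: int = Field(80, ge=1)
    tail_width: int = Field(4, ge=1)

    @field_validator("threshold")
    @classmethod
    def _threshold_range(cls, v):
        if isinstance(v, int) and not 0 <= v <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        return v


class WaveformConfig(_Model):
    method: Literal["centroid", "symmetry"] = "centroid"


class RankConfig(_Model):
    m_contour: int = Field(5, ge=1, le=16)
    m_gray: int = Field(8, ge=1, le=16)
    n_models: int = Field(10, ge=1)
    per_class_train: int = Field(5, ge=1)


class ClassifierConfig(_Model):
    alpha_grid: list[float] = Field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 10)]
    )
    direction: Literal["below", "above"] = "below"
    knn_k: int = Field(10, ge=1)
    knn_normal_cut: Optional[int] = 3
    ovality_band: tuple[float, float] = (1.2, 1.8)

    @field_validator("alpha_grid")
    @classmethod
    def _alphas_in_range(cls, v):
        if not v:
            raise ValueError("alpha grid must not be empty")
        for a in v:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha {a} outside [0, 1]")
        return v


class SvmSettings(_Model):
    gamma: Optional[float] = Field(None, gt=0)
    cost: float = Field(1.0, gt=0)
    cache_mb: float = 40.0
    eps: float = 0.001
    shrinking: bool = True


class RunConfig(_Model):
    """Everything needed to reproduce one experiment run."""

    seed: int = 0
    input: InputConfig = InputConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    waveform: WaveformConfig = WaveformConfig()
    rank: RankConfig = RankConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    svm: SvmSettings = SvmSettings()
    output_dir: Optional[str] = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; an empty file means all defaults.

    Unknown keys are rejected; YAML syntax errors carry line information.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)
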