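from __future__ import annotations

import numpy as np
import pytest

from spermwave.config import RunConfig
from spermwave.fixtures import HeadParams, generate_head, generate_scene
from spermwave.segment import SpermCrop

from tests._oracles import draw_ellipse_mask


@pytest.fixture(scope="session")
def small_scene():
    """A 12+12 scene, large enough for model selection and both SVM classes."""
    return generate_scene(12, 12, seed=11)


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline result on the 12+12 scene."""
    from spermwave.pipeline import run_pipeline

    cfg = RunConfig(seed=11)
    cfg.input.simulate.n_normal = 12
    cfg.input.simulate.n_abnormal = 12
    return run_pipeline(cfg)


@pytest.fixture
def ellipse_mask():
    def _make(a=18.0, b=12.0, angle=0.0, pad=6):
        size = int(2 * a) + 2 * pad + 1
        centre = (size // 2, size // 2)
        return draw_ellipse_mask((size, size), centre, a, b, angle)

    return _make


@pytest.fixture
def disc_mask(ellipse_mask):
    def _make(r=15.0):
        return ellipse_mask(a=r, b=r)

    return _make


@pytest.fixture
def uniform_crop():
    """A disc crop with uniform interior intensity on a bright background."""

    def _make(r=10, value=100, shape=(31, 31)):
        mask = draw_ellipse_mask(shape, (shape[0] // 2, shape[1] // 2), r, r)
        image = np.full(shape, 230, dtype=np.uint8)
        image[mask] = value
        return SpermCrop(image=image, mask=mask, origin=(0, 0))

    return _make


@pytest.fixture
def plain_head():
    """A noise-free tail-free head rendering."""

    def _make(a=18.0, b=12.0, seed=0, **kw):
        params = HeadParams(
            semi_major=a,
            semi_minor=b,
            intensity_noise_sd=0.0,
            **kw,
        )
        canvas = int(2 * params.reach()) + 9
        return generate_head(params, (canvas, canvas), seed=seed)

    return _make
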