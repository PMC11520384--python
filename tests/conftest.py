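"""Shared fixtures: band axes and small synthetic scenes built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hsistress import NoiseModel, make_band_axis
from hsistress.cube_io import SceneMetadata
from hsistress.synthetic_scene import (
    default_models,
    default_panel_region,
    generate_scene,
)

SCENE_SHAPE = (80, 80)


@pytest.fixture(scope="session")
def axis():
    return make_band_axis()


@pytest.fixture(scope="session")
def panel_region():
    return default_panel_region(SCENE_SHAPE)


def make_meta(panel_region, **overrides) -> SceneMetadata:
    kwargs = dict(
        species="soybean",
        treatment="control",
        day_index=0,
        session="noon",
        replicate=1,
        panel_region=panel_region,
        seed=1234,
    )
    kwargs.update(overrides)
    return SceneMetadata(**kwargs)


@pytest.fixture(scope="session")
def noiseless_models():
    return default_models("soybean", scene_shape=SCENE_SHAPE, noise=NoiseModel.none())


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_models, panel_region):
    """Noiseless day-0 control noon scene with its ground-truth plant mask."""
    meta = make_meta(panel_region)
    cube, mask = generate_scene(
        noiseless_models, meta, SCENE_SHAPE, return_mask=True
    )
    return cube, mask, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
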