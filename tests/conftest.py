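"""Shared fixtures: small synthetic scenes rendered once per session."""

import numpy as np
import pytest

from vicar.preprocess import PreprocessConfig
from vicar.synthetic_data import SceneConfig, make_scene, render_series

# Spacers must be large enough (>~115 px) for their detected interior
# plateau to clear the 0.05 ratio filter, so small-canvas test scenes
# widen the circular mask instead of shrinking the spacers.
SMALL = dict(
    rows=512, cols=512, n_frames=4,
    spacer_ring_radius=105, spacer_side_min=115, spacer_side_max=125,
    max_step_px=1.5, max_step_deg=0.2,
)


@pytest.fixture(scope="session")
def small_preprocess_config():
    return PreprocessConfig(mask_diameter_fraction=0.9)


@pytest.fixture(scope="session")
def small_scene():
    return make_scene(SceneConfig(**SMALL), seed=11)


@pytest.fixture(scope="session")
def small_series(small_scene):
    series, truth = render_series(small_scene)
    return series, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
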