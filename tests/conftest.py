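import numpy as np
import pytest

import mitoscreen as ms
from mitoscreen.config import RunConfig
from mitoscreen.workflows import segment_frame


@pytest.fixture(scope="session")
def small_scene():
    """Eight-cell, ten-frame basal scene at the default engulfment rate."""
    return ms.generate_scene(ms.SceneParams(n_cells=8, seed=1))


@pytest.fixture(scope="session")
def small_stack(small_scene):
    return ms.render_timelapse(small_scene)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, uniform-intensity scene for exact round trips."""
    params = ms.SceneParams(
        n_cells=4,
        n_frames=2,
        mito_intensity_cv=0.0,
        noise_model=ms.NoiseModel(gaussian_sd=0.0, poisson_scale=0.0),
        seed=5,
    )
    return ms.generate_scene(params)


@pytest.fixture(scope="session")
def clean_stack(clean_scene):
    return ms.render_timelapse(clean_scene)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_maps(small_stack, run_config):
    """Segmented frame 0 of the small noisy scene."""
    return segment_frame(small_stack, 0, run_config)


@pytest.fixture(scope="session")
def clean_maps(clean_stack, run_config):
    return segment_frame(clean_stack, 0, run_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
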