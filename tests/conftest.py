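import warnings

import numpy as np
import pytest

from mssm.phantom import PhantomConfig, make_phantom_subject
from mssm.workflows import demo_phantom_config


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free phantom with zero subject variation.

    Piecewise-constant construction: sampled intensities away from
    tissue boundaries equal the configured means exactly (up to
    interpolation near boundaries).
    """
    config = PhantomConfig(
        subdivisions=3, base_radius_mm=25.0, thickness_mm=2.5,
        noise_sd=0.0, bias_amplitude=0.0,
        thickness_subject_sd=0.0, thickness_vertex_sd=0.0, gm_subject_sd=0.0,
    )
    return config, make_phantom_subject(config, None, rng_seed=0)


@pytest.fixture(scope="session")
def small_mesh():
    from mssm.phantom import white_icosphere

    return white_icosphere(demo_phantom_config(subdivisions=2))


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
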