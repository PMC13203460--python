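import numpy as np
import pytest

from ovimorph.synth import FlockCalibration, RenderConfig, sample_flock


@pytest.fixture(scope="session")
def default_calibration():
    return FlockCalibration()


@pytest.fixture(scope="session")
def big_flock(default_calibration):
    """10,000-animal flock for the population-moment checks."""
    return sample_flock(10_000, seed=42, calib=default_calibration)


@pytest.fixture(scope="session")
def small_flock():
    """A 30-animal flock for the fast mechanism tests."""
    return sample_flock(30, seed=7)


@pytest.fixture(scope="session")
def clean_render_config():
    """Noise-free renders (deterministic geometry only)."""
    return RenderConfig(background_noise_sd=0.0, texture_noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
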