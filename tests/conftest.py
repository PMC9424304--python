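import numpy as np
import pytest

from uvplume import ConeCatchMapper, make_calibration, make_specimen_image, make_world


@pytest.fixture(scope="session")
def world():
    return make_world(seed=1)


@pytest.fixture(scope="session")
def calibration(world):
    return make_calibration(world, n_spectra=250, seed=2)


@pytest.fixture(scope="session")
def mapper(world, calibration):
    X, Y, _ = calibration
    return ConeCatchMapper().fit(X, Y)


@pytest.fixture(scope="session")
def clean_image(world):
    """Noise-free specimen with eye disc, no label, gain 1.3."""
    return make_specimen_image(world, gain=1.3, noise_sd=0.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
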