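import numpy as np
import pytest

import perivene as pv


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless phantom at coarse spacing, shared across tests."""
    spec = pv.default_phantom_spec(spacing=(0.75, 0.75, 1.5), noise_sd=0.0, seed=0)
    image, truth = pv.build_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same anatomy with 5% (of the high-signal mean) Gaussian noise."""
    spec = pv.default_phantom_spec(spacing=(0.75, 0.75, 1.5), noise_sd=10.0, seed=3)
    image, truth = pv.build_phantom(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
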