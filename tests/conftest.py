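import numpy as np
import pytest

from ssrdcm.forward import default_freqs
from ssrdcm.params import default_noise, default_params


@pytest.fixture(scope="session")
def fb_params():
    return default_params("FB")


@pytest.fixture(scope="session")
def noise():
    return default_noise()


@pytest.fixture(scope="session")
def freqs():
    return default_freqs()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def decoupled_params():
    """Two sources with all couplings removed: five independent kernels each."""
    return default_params("FB", overrides={
        "gamma": (0.0, 0.0, 0.0, 0.0, 0.0),
        "forward_strength": 0.0,
        "backward_strength": 0.0,
    })
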