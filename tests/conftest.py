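import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spheroidsim as ss

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def defaults() -> ss.ModelParameters:
    return ss.default_parameters()


@pytest.fixture
def tiny_params() -> ss.ModelParameters:
    """Small, fast parameter set with the full biology switched on."""
    return ss.default_parameters().replace(
        N0=500, Nr0=349, Ny0=17, Ng0=134, L=600.0, I=31, ro_init=100.0, T=4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
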