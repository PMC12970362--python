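import numpy as np
import pytest
from hypothesis import settings

from slicdd.simulators import simulate_pde

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def burgers_data():
    return simulate_pde("burgers")


@pytest.fixture(scope="session")
def kdv_data():
    return simulate_pde("kdv")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
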