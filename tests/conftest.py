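import numpy as np
import pytest

from spiralchaos.grid import Grid
from spiralchaos.integrator import NumericsConfig
from spiralchaos.models import load_bocf_params, load_tnnp_params


@pytest.fixture(scope="session")
def bocf_params():
    return load_bocf_params()


@pytest.fixture(scope="session")
def tnnp_params():
    return load_tnnp_params()


@pytest.fixture(scope="session")
def bocf_cfg():
    return NumericsConfig.bocf_defaults()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return Grid(40, 40, 1.0)
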