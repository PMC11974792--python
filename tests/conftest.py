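import numpy as np
import pytest

from melsim.config import load_defaults
from melsim.pulse_optics import FrequencyGrid, make_supercontinuum


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def default_field(grid):
    return make_supercontinuum(grid=grid)


@pytest.fixture(scope="session")
def defaults():
    return load_defaults()


@pytest.fixture(scope="session")
def params(defaults):
    p = defaults.photocycle_params()
    p.ensure_z_ref()
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
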