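import numpy as np
import pytest

from tmesim.grid import ParameterTable, build_grid, make_preset


@pytest.fixture(scope="session")
def params():
    return ParameterTable.default()


@pytest.fixture()
def unit_grid():
    return build_grid((0.4, 0.4, 0.4), (9, 9, 9))


@pytest.fixture()
def unit_config():
    return make_preset("unit", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
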