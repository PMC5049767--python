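import numpy as np
import pytest

from tumorangio import default_config
from tumorangio.fixtures import FixtureSpec, make_fixture


@pytest.fixture
def cfg():
    """Baseline parameter set."""
    return default_config()


@pytest.fixture
def small_cfg():
    """A 21x21 lattice with the standard rates, for fast unit tests."""
    return default_config(grid_n=21, h=1.0 / 20, n_init_cells=9,
                          snapshot_hours=(), record_stride_hours=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_cell_state(small_cfg):
    """21x21 state with one proliferative cell at the center, c = 1."""
    return make_fixture(FixtureSpec(grid_n=21, cells=((10, 10),)))
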