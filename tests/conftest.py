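import numpy as np
import pytest

from gbmsim.grid import Grid
from gbmsim.params import ModelParams
from gbmsim.solver import SeedSpec, SimulationConfig


@pytest.fixture
def grid():
    return Grid(nx=40, ny=40)


@pytest.fixture
def params():
    return ModelParams.single_cell()


@pytest.fixture
def gog_params():
    return ModelParams.gog()


@pytest.fixture
def small_config(grid):
    """Fast configuration on a 40x40 grid for end-to-end tests."""
    return SimulationConfig(grid=grid, t_max=400.0, snapshot_interval=12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
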