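import numpy as np
import pytest

from striatnet.cell import CellParams, DriveSpec, simulate_cell
from striatnet.network import NetworkParams, build_network, run_network


@pytest.fixture(scope="session")
def cell_params():
    return CellParams()


@pytest.fixture(scope="session")
def max_drive_trace(cell_params):
    """10 s trace of an isolated MSN at the top of the drive range."""
    return simulate_cell(cell_params, DriveSpec(increment=2.0e-5, duration_s=10.0))


@pytest.fixture(scope="session")
def small_net_raster():
    """A 40-cell, 30 s mid-range network run shared across tests."""
    params = NetworkParams(n_cells=40, g_i=0.008, g_e=1.0e-5,
                           duration_s=30.0, seed=7)
    net = build_network(params)
    return net, run_network(net)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
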