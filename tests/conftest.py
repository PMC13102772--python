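import numpy as np
import pytest

from tiesim.cable import CableParams, SimConfig
from tiesim.tissue import default_skin_model


@pytest.fixture(scope="session")
def model():
    return default_skin_model()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def cable_params():
    return CableParams()


@pytest.fixture(scope="session")
def straight_axon_positions():
    """51 nodes along x at 0.1 mm spacing (positions only)."""
    pos = np.zeros((51, 3))
    pos[:, 0] = np.arange(51) * 0.1
    return pos


@pytest.fixture(scope="session")
def halfspace_solutions():
    """Phasor solutions of the homogeneous half-space fixture at two
    spacings, shared by the analytic-agreement and convergence tests."""
    from tiesim.field import assemble_grid, default_boundaries, solve_phasor
    from tiesim.fixtures import make_fixture

    fx = make_fixture("homogeneous-halfspace")
    out = {}
    for h in (0.5, 0.25):
        grid = assemble_grid(fx["model"], 1000.0, h)
        bd = default_boundaries(grid)
        out[h] = (solve_phasor(grid, bd, "stim1"), bd)
    return fx, out
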