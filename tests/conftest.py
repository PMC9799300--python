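import numpy as np
import pytest

from grnabc.core import make_grid, make_parameters
from grnabc.datasets import generate_ensemble, generate_grid_data
from grnabc.simulators import SimulationConfig


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down sampling layout used by the desk-scale tests."""
    return SimulationConfig(t_burn=200.0, n_samples=20, dt_sample=5.0, dt_bd=0.01, seed=0)


@pytest.fixture(scope="session")
def wmm_grid_small(fast_config):
    """4x4 grid of WMM ensembles (8 trajectories each), shared across tests."""
    grid = make_grid(4, 4)
    from dataclasses import replace

    return generate_grid_data(grid, "WMM", 8, replace(fast_config, seed=42))


@pytest.fixture(scope="session")
def wmm_center_ensemble(fast_config):
    """Observed-data stand-in: WMM ensemble at the base point (D=0.6, chi=1)."""
    from dataclasses import replace

    return generate_ensemble("WMM", 0.6, 1.0, 8, replace(fast_config, seed=4242))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
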