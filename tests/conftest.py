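import math

import numpy as np
import pytest

from txswitch.model import CellParams, SwitchFunction, TimeSeries


@pytest.fixture(scope="session")
def scenario1_fn():
    return SwitchFunction(np.array([12.0, 20.0]), np.array([6.0, 20.0, 2.0]),
                          42.0)


@pytest.fixture(scope="session")
def scenario1_params(scenario1_fn):
    return CellParams(scenario1_fn, alpha=3.0, delta_m=1.0, delta_p=0.7,
                      kappa=1.0, sigma_eps=2.0, M0=6, P0=26)


@pytest.fixture(scope="session")
def constant_params():
    """Constant transcription at the scenario-1 initial rate."""
    fn = SwitchFunction.constant(6.0, 42.0)
    return CellParams(fn, alpha=3.0, delta_m=1.0, delta_p=0.7, kappa=1.0,
                      sigma_eps=2.0, M0=6, P0=26)


@pytest.fixture(scope="session")
def quarter_hour_grid():
    return np.arange(0.0, 42.25, 0.25)


@pytest.fixture(scope="session")
def short_series(scenario1_params):
    """A short synthetic observation series from the exact process."""
    from txswitch.ssa import simulate_on_grid
    grid = np.arange(0.0, 10.25, 0.25)
    rng = np.random.default_rng(123)
    path = simulate_on_grid(scenario1_params, grid, seed=123)
    y = path[:, 1] * scenario1_params.kappa + rng.normal(0, 2.0, grid.size)
    return TimeSeries(grid, y, cell_id="short")


@pytest.fixture(scope="session")
def degradation_priors():
    from txswitch.priors import PriorConfig
    return PriorConfig(mu_dm=0.0, sd_dm=0.1, mu_dp=math.log(0.7), sd_dp=0.1)
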