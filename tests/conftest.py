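import numpy as np
import pytest

from maxcalbench.ssa import FrameSeries, SimulationConfig, simulate_ssa


@pytest.fixture(scope="session")
def sgaa_48h_trajectories():
    """Twenty 48-hour SGAA trajectories at the default circuit rates,
    shared across tests that only need realistic switch-like data."""
    from maxcalbench.circuits import build_sgaa_generator

    net = build_sgaa_generator()
    cfg = SimulationConfig(
        t_end=43200.0 + 48 * 3600.0, delta_t=300.0,
        n_trajectories=20, burn_in=43200.0, rng_seed=2024,
    )
    return simulate_ssa(net, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(values, delta_t=300.0, labels=("A",)):
    return FrameSeries(delta_t, np.asarray(values), list(labels))
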