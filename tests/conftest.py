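import numpy as np
import pytest

import matefit as mf


@pytest.fixture(scope="session")
def params():
    """Reference parameter set used across the suite."""
    return mf.ModelParams(alpha=0.5, delta=1.0, mu_x=10.0, mu_y=12.0,
                          sigma_x=2.0, sigma_y=2.0)


@pytest.fixture(scope="session")
def sim_data(params):
    """One moderately sized simulated dataset (seed-pinned)."""
    cfg = mf.SimulationConfig(params=params, n_pairs=300, n_singles=300,
                              seed=42)
    return mf.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_fit(sim_data):
    return mf.fit_mle(sim_data)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
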