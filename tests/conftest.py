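import numpy as np
import pytest

from mmjoint import JointModel, SimulationCondition, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset with its generating truth."""
    cond = SimulationCondition(N=120, I=9, K=3, rho_theta_tau=-0.4, seed=42)
    data, persons, items = simulate_dataset(cond)
    return cond, data, persons, items


@pytest.fixture(scope="session")
def fitted_small(small_sim):
    """A short but converged fit of the small dataset, shared across tests."""
    _, data, persons, items = small_sim
    model = JointModel(n_iterations=800, n_burnin=400, seed=7)
    model.fit(data)
    return data, model, persons, items


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
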