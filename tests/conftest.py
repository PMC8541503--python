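import numpy as np
import pytest

from mmrisk import RiskScoreModel, SimulationConfig, simulate_cohort, simulate_validation_cohort

COHORT_SEED = 1234


def make_survival(rng, n, cens_frac=0.3, scale=100.0, eta=None):
    """Random right-censored survival data for tests."""
    if eta is None:
        eta = np.zeros(n)
    t = rng.exponential(scale=scale * np.exp(-eta))
    if cens_frac > 0:
        c = rng.exponential(scale=scale * (1 - cens_frac) / cens_frac, size=n)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t, c) + 1e-9
    event = (t <= c).astype(int)
    from mmrisk import SurvivalData

    return SurvivalData([f"s{i}" for i in range(n)], time, event)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def fitted(cohort):
    counts, surv, _ = cohort
    return RiskScoreModel(counts, surv).fit()


@pytest.fixture(scope="session")
def validation_cohort(sim_config, cohort):
    _, _, truth = cohort
    return simulate_validation_cohort(sim_config, truth, n_samples=150)
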