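import numpy as np
import pandas as pd
import pytest

from sleepmr.synth import SimScenario, simulate_cohort


@pytest.fixture(scope="session")
def strong_instrument_cohort():
    """Moderate cohort with a strong instrument and a real causal effect.

    Shared across tests that only need a realistic analysis-ready
    dataset (prevalent rows already excluded).
    """
    sc = SimScenario(
        n=6000, m=30, variance_explained=0.05,
        true_log_hr=float(np.log(1.5)), baseline_hazard_rate=0.01,
        prevalent_fraction=0.0, seed=42,
    )
    cohort, genotypes, variants = simulate_cohort(sc)
    return sc, cohort, genotypes, variants


@pytest.fixture(scope="session")
def null_effect_cohort():
    """Cohort with no causal effect, no confounding, no pleiotropy."""
    sc = SimScenario(
        n=6000, m=30, variance_explained=0.05,
        true_log_hr=0.0, confounder_effect_on_exposure=0.0,
        confounder_effect_on_log_hazard=0.0,
        baseline_hazard_rate=0.01, prevalent_fraction=0.0, seed=7,
    )
    cohort, genotypes, variants = simulate_cohort(sc)
    return sc, cohort, genotypes, variants


def make_group_survival(groups, hr_by_group, n_per=None, lam0=0.02,
                        censor=12.0, seed=0):
    """Exponential survival times by group label with given hazard ratios."""
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    rate = lam0 * np.array([hr_by_group[g] for g in groups])
    t = rng.exponential(1.0 / rate)
    time = np.minimum(t, censor)
    event = (t <= censor).astype(int)
    return pd.DataFrame({"time": time, "event": event})
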