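import numpy as np
import pandas as pd
import pytest

from wcetrial.simulate import SimConfig, TrueModel, simulate_cohort
from wcetrial.trial_data import build_counting_process, shift_baseline


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    cfg = SimConfig(n_patients=120)
    return simulate_cohort(cfg, TrueModel(), seed=20240917)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    c = small_cohort
    cohort = shift_baseline(c.patients, c.doses, c.updates, c.outcomes)
    return cohort, build_counting_process(cohort)


@pytest.fixture()
def four_subject_table():
    """Closed-form Cox fixture: score equation e^(2b) = 2."""
    return pd.DataFrame({
        "patient_id": [1, 2, 3, 4],
        "start": [0.0, 0.0, 0.0, 0.0],
        "stop": [1.0, 2.5, 2.0, 3.0],
        "event": [True, False, True, True],
        "x": [1.0, 1.0, 0.0, 0.0],
    })


@pytest.fixture(scope="session")
def survival_frame():
    """Moderate right-censored survival data with two covariates, no ties."""
    rng = np.random.default_rng(7)
    n = 150
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.5, size=n).astype(float)
    T = rng.exponential(1 / (0.1 * np.exp(0.5 * x1 - 0.3 * x2)))
    C = rng.uniform(0.5, 15, size=n)
    stop = np.minimum(T, C)
    return pd.DataFrame({
        "patient_id": np.arange(n), "start": 0.0, "stop": stop,
        "event": T <= C, "x1": x1, "x2": x2,
    })
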