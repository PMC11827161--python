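import numpy as np
import pandas as pd
import pytest

import apotraj
from apotraj.apo import build_analysis_table, derive_apo_profiles


def make_pregnancy(woman_id=1, preg_index=1, t_start=0.0, t_end=0.75,
                   outcome="live birth", **flags):
    row = {
        "woman_id": woman_id,
        "preg_index": preg_index,
        "t_start": t_start,
        "t_end": t_end,
        "outcome": outcome,
        "gestational_hypertension": 0.0,
        "preeclampsia": 0.0,
        "gestational_diabetes": 0.0,
        "ptb_spontaneous": 0.0,
        "ptb_indicated": 0.0,
        "sga": 0.0,
        "lga": 0.0,
        "congenital_anomaly": 0.0,
    }
    row.update(flags)
    return row


def pregnancies_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_cfg():
    return apotraj.default_config()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 4,000-woman cohort (systolic BP only) for pipeline tests."""
    return apotraj.simulate_cohort(4000, seed=314, outcomes=["sbp"])


@pytest.fixture(scope="session")
def small_sbp_table(small_cohort):
    c = small_cohort
    profiles = derive_apo_profiles(c.pregnancies)
    return build_analysis_table(
        c.measurements, c.pregnancies, profiles, c.women, "sbp", exposure="n_apos"
    )


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free cohort: zero variance components and covariate effects."""
    cfg = apotraj.default_config().updated(
        {
            "truth": {
                "noise": {o: {"intercept_sd": 0.0, "residual_sd": 0.0}
                          for o in apotraj.OUTCOMES},
                "covariate_effects": {
                    o: {"smoking_ever": 0.0, "townsend_quintile": 0.0}
                    for o in apotraj.OUTCOMES
                },
                "fasting_effect": 0.0,
            }
        }
    )
    return apotraj.simulate_cohort(3000, config=cfg, seed=99, outcomes=["sbp"]), cfg


def rng_design(n_groups, m, p=3, seed=0, sigma_u=1.0, sigma_e=1.0,
               beta=None):
    """Small mixed-model test instance with known parameters."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), m)
    n = n_groups * m
    x = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    if beta is None:
        beta = np.arange(1, p + 1, dtype=float)
    u = rng.normal(0.0, sigma_u, n_groups)
    y = x @ np.asarray(beta) + u[g] + rng.normal(0.0, sigma_e, n)
    return x, y, g, np.asarray(beta)
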