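"""Shared fixtures: small simulated datasets reused across test modules.

All fixtures are generated at test time from the package's own simulator;
nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ncchdps import (
    SimulationConfig,
    assemble_cohort,
    assemble_ncc,
    simulate_cohort,
)

TRUE_LOG_HR = np.log(0.7)


def null_config(n: int, seed: int, **kw) -> SimulationConfig:
    """No-confounding configuration: the latent confounder touches nothing."""
    return SimulationConfig(
        n_subjects=n,
        seed=seed,
        confounder_to_exposure=0.0,
        confounder_to_hazard=0.0,
        code_confounder_loading=0.0,
        **kw,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Confounded simulation, 500 subjects."""
    return simulate_cohort(SimulationConfig(n_subjects=500, seed=5))


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    tables, _ = small_sim
    return assemble_cohort(tables).cohort


@pytest.fixture(scope="session")
def small_ncc(small_cohort):
    return assemble_ncc(small_cohort, m=4, seed=17)


@pytest.fixture(scope="session")
def null_mc_estimates():
    """20 no-confounding replicates (n=600, true HR 0.7): per-seed NCC
    conditional-logistic estimates, reused by calibration-style tests."""
    from ncchdps import fit_conditional_logistic

    out = []
    for seed in range(20):
        tables, _ = simulate_cohort(null_config(600, 100 + seed))
        cohort = assemble_cohort(tables).cohort
        ncc = assemble_ncc(cohort, m=4, seed=seed)
        out.append(fit_conditional_logistic(ncc.data))
    return out


def toy_cohort() -> pd.DataFrame:
    """Hand-built 8-person cohort with one matching stratum, used by the
    NCC fixtures that need fully enumerable risk sets."""
    return pd.DataFrame(
        {
            "person_id": [f"X{i}" for i in range(8)],
            "index_date": "2000-01-01",
            "age_at_index": [40.0 + i for i in range(8)],
            "sex": ["female"] * 4 + ["male"] * 4,
            "income_quintile": 3,
            "cci_category": "0",
            "calendar_period": "2000-2005",
            "followup_days": [10, 20, 20, 30, 40, 50, 60, 70],
            "event": [True, True, False, False, True, False, False, False],
            "exposure_switch_day": [np.nan, 5.0, np.nan, 15.0, 35.0, np.nan, 25.0, np.nan],
        }
    )
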