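"""Outcome-model oracles: exhaustive conditional-likelihood enumeration,
the McNemar identity, closed-form Cox fixtures, and diagnostic calibration."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.stats import kstest

from ncchdps import (
    fit_conditional_logistic,
    fit_time_varying_cox,
    km_logrank,
    ph_check,
    split_counting_process,
)
from ncchdps.models import conditional_loglik_parts


# ---------------------------------------------------------------------------
# conditional likelihood: brute-force enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_loglik(beta, X, case, set_ids, weights):
    """Independent oracle: per set, the case probability's denominator is
    built by explicitly enumerating every within-set case assignment.
    Complex-safe so the gradient can be checked by complex-step."""
    beta = np.asarray(beta)
    total = 0.0 + 0.0j if np.iscomplexobj(beta) else 0.0
    for s in np.unique(set_ids):
        rows = np.flatnonzero(set_ids == s)
        c = rows[case[rows]][0]
        eta_c = X[c] @ beta
        denom = 0.0
        for assignment in rows:  # every member as hypothetical case
            denom = denom + weights[assignment] * np.exp(X[assignment] @ beta)
        total = total + weights[c] * (
            np.log(weights[c]) + eta_c - np.log(denom)
        ) - weights[c] * np.log(weights[c])
    return total


def enumerate_gradient(beta, X, case, set_ids, weights):
    h = 1e-200
    grad = np.empty(len(beta))
    for j in range(len(beta)):
        bc = np.asarray(beta, dtype=complex).copy()
        bc[j] += 1j * h
        grad[j] = enumerate_loglik(bc, X, case, set_ids, weights).imag / h
    return grad


def random_fixture(rng, n_sets=6, max_size=5, p=2):
    rows = []
    for s in range(n_sets):
        size = rng.integers(2, max_size + 1)
        case_pos = rng.integers(0, size)
        for j in range(size):
            rows.append((s, j == case_pos, *rng.normal(size=p)))
    df = pd.DataFrame(rows, columns=["set_id", "is_case", "x0", "x1"])
    return df


@pytest.mark.parametrize("weighted", [False, True])
def test_loglik_and_gradient_match_enumeration(weighted):
    rng = np.random.default_rng(11)
    for trial in range(5):
        df = random_fixture(rng)
        X = df[["x0", "x1"]].to_numpy()
        case = df["is_case"].to_numpy(dtype=bool)
        set_ids = df["set_id"].to_numpy()
        w = rng.uniform(0.5, 2.0, len(df)) if weighted else np.ones(len(df))
        starts = np.flatnonzero(np.r_[True, set_ids[1:] != set_ids[:-1]])
        for beta in ([0.0, 0.0], [0.5, -1.0], list(rng.normal(size=2))):
            beta = np.asarray(beta)
            ll, scores, _ = conditional_loglik_parts(beta, X, case, starts, w)
            ll_oracle = enumerate_loglik(beta, X, case, set_ids, w)
            grad_oracle = enumerate_gradient(beta, X, case, set_ids, w)
            assert abs(ll - ll_oracle) < 1e-10
            assert np.max(np.abs(scores.sum(axis=0) - grad_oracle)) < 1e-10


def test_gradient_vanishes_at_reported_optimum(small_ncc):
    est = fit_conditional_logistic(small_ncc.data)
    assert est.converged
    assert est.diagnostics["max_abs_score"] < 1e-6


def test_mcnemar_identity_on_one_to_one_binary_sets():
    """For 1:1 sets with a single binary covariate the conditional-logistic
    estimate is exactly the log discordant-pair ratio."""
    rows = []
    discordant = [(True, False)] * 4 + [(False, True)] * 2
    concordant = [(True, True), (False, False)]
    for s, (case_exp, ctrl_exp) in enumerate(discordant + concordant):
        rows.append({"set_id": s, "is_case": True, "exposed": case_exp})
        rows.append({"set_id": s, "is_case": False, "exposed": ctrl_exp})
    df = pd.DataFrame(rows)
    est = fit_conditional_logistic(df, adjust=())
    assert est.log_hr == pytest.approx(np.log(4 / 2), abs=1e-8)


def test_unit_weights_equal_no_weights(small_ncc):
    a = fit_conditional_logistic(small_ncc.data)
    b = fit_conditional_logistic(small_ncc.data, weights=np.ones(len(small_ncc.data)))
    assert a.log_hr == pytest.approx(b.log_hr, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


def test_against_statsmodels_conditional_logit(small_ncc):
    """Independent cross-check of the unweighted fit."""
    from statsmodels.discrete.conditional_models import ConditionalLogit

    d = small_ncc.data.copy()
    d["sex_male"] = (d["sex"] == "male").astype(float)
    ref = ConditionalLogit(
        d["is_case"].astype(float),
        d[["exposed", "age_at_index", "sex_male"]].astype(float),
        groups=d["set_id"],
    ).fit(disp=0)
    est = fit_conditional_logistic(small_ncc.data)
    assert est.coefficients.to_numpy() == pytest.approx(ref.params.values, abs=5e-5)


def test_within_set_constant_covariate_dropped(small_ncc):
    d = small_ncc.data.copy()
    d["flat"] = 1.0
    est = fit_conditional_logistic(d, adjust=("age_at_index", "sex", "flat"))
    assert "flat" in est.diagnostics["dropped_covariates"]
    ref = fit_conditional_logistic(small_ncc.data)
    assert est.log_hr == pytest.approx(ref.log_hr, abs=1e-10)


def test_sandwich_se_close_to_model_se_when_well_specified(null_mc_estimates):
    ratios = [e.se / e.model_se for e in null_mc_estimates]
    assert all(r >= 0 for r in ratios)
    assert 0.7 <= np.mean(ratios) <= 1.4


# ---------------------------------------------------------------------------
# counting process + Cox
# ---------------------------------------------------------------------------


def one_person_cohort(followup, event, switch):
    return pd.DataFrame(
        {
            "person_id": ["p"],
            "age_at_index": [50.0],
            "sex": ["female"],
            "income_quintile": [1],
            "cci_category": ["0"],
            "calendar_period": ["1996-1999"],
            "followup_days": [followup],
            "event": [event],
            "exposure_switch_day": [switch],
        }
    )


def test_split_switch_day_zero_single_exposed_row():
    rows = split_counting_process(one_person_cohort(100, True, 0.0))
    assert len(rows) == 1
    assert rows.loc[0, "exposed"] and rows.loc[0, "event"]
    assert (rows.loc[0, "start"], rows.loc[0, "stop"]) == (0.0, 101.0)


def test_split_exposed_death_bookkeeping():
    """Death during day 100 occurs at time 101; the switch splits the
    person-time at day 40."""
    rows = split_counting_process(one_person_cohort(100, True, 40.0))
    assert len(rows) == 2
    first, second = rows.iloc[0], rows.iloc[1]
    assert (first["start"], first["stop"]) == (0.0, 40.0)
    assert not first["exposed"] and not first["event"]
    assert (second["start"], second["stop"]) == (40.0, 101.0)
    assert second["exposed"] and second["event"]


def test_split_never_exposed_censored():
    rows = split_counting_process(one_person_cohort(50, False, np.nan))
    assert len(rows) == 1
    assert not rows.loc[0, "exposed"] and not rows.loc[0, "event"]


def test_split_rejects_switch_after_followup():
    with pytest.raises(ValueError):
        split_counting_process(one_person_cohort(50, False, 60.0))


def test_time_varying_cox_matches_closed_form():
    """Four-person fixture whose partial likelihood maximum is
    analytically -log(2)/2 for the exposure coefficient."""
    cohort = pd.concat(
        [
            one_person_cohort(0, True, np.nan),   # unexposed, event at time 1
            one_person_cohort(2, True, 0.0),      # exposed, event at time 3
            one_person_cohort(3, False, 0.0),     # exposed, censored
            one_person_cohort(3, False, np.nan),  # unexposed, censored
        ],
        ignore_index=True,
    )
    cohort["person_id"] = ["a", "b", "c", "d"]
    rows = split_counting_process(cohort)
    est = fit_time_varying_cox(rows, adjust=(), strata=())
    assert est.log_hr == pytest.approx(-0.5 * np.log(2), abs=1e-5)


# ---------------------------------------------------------------------------
# KM / log-rank / PH diagnostics
# ---------------------------------------------------------------------------


def test_km_no_events_survival_one():
    df = pd.DataFrame(
        {"followup_days": [5, 10], "event": [False, False], "exposed": [True, False]}
    )
    curves, test = km_logrank(df)
    for c in curves.values():
        assert (c.to_numpy() == 1.0).all()


def test_logrank_zero_for_identical_duplicated_groups():
    base = pd.DataFrame(
        {"followup_days": [3, 6, 9], "event": [True, True, False]}
    )
    df = pd.concat(
        [base.assign(exposed=True), base.assign(exposed=False)], ignore_index=True
    )
    _, test = km_logrank(df)
    assert test.test_statistic == pytest.approx(0.0, abs=1e-12)


def test_logrank_matches_hand_calculation():
    """2 groups x 2 subjects, one event per group at distinct times:
    chi-square statistic is 1/17 by direct tabulation."""
    df = pd.DataFrame(
        {
            "followup_days": [1, 4, 2, 4],
            "event": [True, False, True, False],
            "exposed": [True, True, False, False],
        }
    )
    _, test = km_logrank(df)
    assert test.test_statistic == pytest.approx(1 / 17, rel=1e-10)


def _null_cox_fit(seed, n=150):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(1.0, size=n)  # x has no effect; PH holds trivially
    e = t < 2.0
    df = pd.DataFrame({"t": np.minimum(t, 2.0), "e": e, "x": x})
    cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    from ncchdps.models import EffectEstimate

    return EffectEstimate(
        log_hr=float(cph.params_["x"]), se=float(cph.standard_errors_["x"]),
        estimator="cox", n=n, model=cph, fit_data=df,
    )


def test_ph_check_calibrated_under_proportional_hazards():
    """Null p-values: rejection rate near alpha and roughly uniform."""
    pvals = np.array([ph_check(_null_cox_fit(s))["x"] for s in range(100)])
    rate = np.mean(pvals < 0.05)
    mc_se = np.sqrt(0.05 * 0.95 / 100)
    assert abs(rate - 0.05) <= 2 * mc_se + 1e-12
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_ph_check_detects_strong_time_varying_effect():
    """Crossing hazards (treated group's hazard drops from 3 to 0.1 at
    t=0.5 while the control hazard stays 0.7) grossly violate
    proportionality; the check should reject hard."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        n = 100
        x = np.r_[np.ones(n), np.zeros(n)]
        e1 = rng.exponential(1.0, 2 * n)
        t = np.where(
            x == 1,
            np.where(e1 < 1.5, e1 / 3.0, 0.5 + (e1 - 1.5) / 0.1),
            e1 / 0.7,
        )
        df = pd.DataFrame({"t": np.minimum(t, 4.0), "e": t < 4.0, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        from ncchdps.models import EffectEstimate

        fit = EffectEstimate(
            log_hr=float(cph.params_["x"]), se=float(cph.standard_errors_["x"]),
            estimator="cox", n=len(df), model=cph, fit_data=df,
        )
        hits += ph_check(fit)["x"] < 0.01
    assert hits >= 9


def test_ph_check_on_time_varying_fit(small_cohort):
    rows = split_counting_process(small_cohort)
    est = fit_time_varying_cox(rows)
    pvals = ph_check(est)
    assert set(pvals.index) >= {"exposed", "age_at_index"}
    assert ((pvals > 0) & (pvals <= 1)).all()
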