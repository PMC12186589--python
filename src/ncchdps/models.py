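"""Outcome models: conditional logistic regression for matched sets,
full-cohort Cox models, and survival diagnostics.

The primary estimator is a (optionally IPT-weighted) conditional logistic
regression stratified by matched set, fitted by Newton-Raphson on the
conditional likelihood

    l(beta) = sum_s w_case [ eta_case - log sum_{j in s} w_j exp(eta_j) ],

which at unit weights is the exact conditional likelihood of a 1:m matched
set given one case per set.  Standard errors come from White's sandwich
estimator clustered on matched set.  Comparators: a full-cohort Cox model
with the exposure as a time-varying covariate (counting-process rows split
at the switch day), and the deliberately naive time-fixed "ever exposed"
Cox fit that exhibits immortal time bias.

Counting-process time convention: a death during follow-up day ``d`` occurs
at time ``d + 1``, so the Cox risk set at each event time coincides exactly
with the incidence-density risk set {persons with followup_days >= d}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5% quantile; 95% CI multiplier


class EstimationError(RuntimeError):
    """The requested model cannot be estimated from the given data."""


@dataclass
class EffectEstimate:
    """A log-hazard-ratio estimate with its sandwich standard error."""

    log_hr: float
    se: float
    estimator: str
    n: int
    coefficients: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    model_se: float = np.nan
    converged: bool = True
    flagged: str | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)
    model: Any = field(default=None, repr=False)
    fit_data: Any = field(default=None, repr=False)

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_hr - Z95 * self.se)),
            float(np.exp(self.log_hr + Z95 * self.se)),
        )

    def summary_row(self) -> dict[str, float | str | int]:
        lo, hi = self.ci95
        return {
            "estimator": self.estimator,
            "log_hr": self.log_hr,
            "se": self.se,
            "hr": self.hr,
            "ci_low": lo,
            "ci_high": hi,
            "n": self.n,
        }


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix; object/categorical columns are dummy-coded."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        series = df[cov]
        if series.dtype == bool:
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        elif np.issubdtype(series.dtype, np.number):
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def conditional_loglik_parts(
    beta: np.ndarray,
    X: np.ndarray,
    case: np.ndarray,
    starts: np.ndarray,
    weights: np.ndarray,
):
    """Log-likelihood, per-set scores, and Hessian of the weighted
    conditional likelihood.  Rows must be sorted by set; ``starts`` indexes
    the first row of each set."""
    eta = X @ beta
    logw = np.log(weights)
    z = logw + eta
    # Stable per-set logsumexp via a per-row broadcast of the set max.
    set_of_row = np.repeat(np.arange(len(starts)), np.diff(np.append(starts, len(z))))
    zmax = np.maximum.reduceat(z, starts)
    ez = np.exp(z - zmax[set_of_row])
    denom = np.add.reduceat(ez, starts)
    lse = zmax + np.log(denom)
    pi = ez / denom[set_of_row]  # within-set softmax over weighted eta

    case_rows = np.flatnonzero(case)
    w_case = weights[case_rows]
    loglik = float(np.sum(w_case * (eta[case_rows] - lse)))

    xbar = np.empty((len(starts), X.shape[1]))
    for j in range(X.shape[1]):
        xbar[:, j] = np.add.reduceat(pi * X[:, j], starts)
    scores = w_case[:, None] * (X[case_rows] - xbar)

    # Hessian: -sum_s w_case ( sum_j pi_j x_j x_j' - xbar xbar' )
    p = X.shape[1]
    outer = X[:, :, None] * X[:, None, :]
    m2 = np.add.reduceat(pi[:, None, None] * outer, starts, axis=0)
    hess = -np.einsum("s,sij->ij", w_case, m2 - xbar[:, :, None] * xbar[:, None, :])
    return loglik, scores, hess.reshape(p, p)


def fit_conditional_logistic(
    ncc_data: pd.DataFrame,
    adjust: Sequence[str] = ("age_at_index", "sex"),
    weights: np.ndarray | pd.Series | None = None,
    exposure_col: str = "exposed",
    set_col: str = "set_id",
    case_col: str = "is_case",
    tol: float = 1e-8,
    max_iter: int = 60,
) -> EffectEstimate:
    """Weighted conditional logistic regression stratified by matched set.

    Parameters
    ----------
    ncc_data : long-format matched sets (one row per member).
    adjust : covariates adjusted for in addition to the exposure.
    weights : optional per-row stabilized IPT weights.

    Returns an :class:`EffectEstimate` whose ``log_hr`` / ``se`` refer to
    the exposure coefficient with the sandwich SE clustered on matched set.
    """
    df = ncc_data.sort_values([set_col], kind="stable").reset_index(drop=True)
    if weights is not None:
        w = np.asarray(
            weights.reindex(ncc_data.index) if isinstance(weights, pd.Series) else weights,
            dtype=float,
        )
        w = w[np.argsort(ncc_data[set_col].to_numpy(), kind="stable")]
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")
    else:
        w = np.ones(len(df))

    X, names = _design_matrix(df, [exposure_col, *adjust])
    set_ids = df[set_col].to_numpy()
    starts = np.flatnonzero(np.r_[True, set_ids[1:] != set_ids[:-1]])
    case = df[case_col].to_numpy(dtype=bool)
    counts = np.diff(np.append(starts, len(df)))
    if not np.all(np.add.reduceat(case.astype(int), starts) == 1):
        raise ValueError("each matched set must contain exactly one case")

    # Covariates with no within-set variation anywhere are inestimable.
    keep: list[int] = []
    dropped: list[str] = []
    set_of_row = np.repeat(np.arange(len(starts)), counts)
    for j, name in enumerate(names):
        col = X[:, j]
        first = col[starts][set_of_row]
        if np.all(col == first):
            dropped.append(name)
        else:
            keep.append(j)
    if dropped:
        logger.info("dropping within-set-constant covariate(s): %s", dropped)
    if names[0] in dropped:
        raise EstimationError(
            "exposure shows no within-set variation; effect not identifiable"
        )
    X = X[:, keep]
    names = [names[j] for j in keep]

    n_uninformative = int(
        np.sum(
            [
                np.all(X[s : s + c] == X[s]) if c > 0 else True
                for s, c in zip(starts, counts)
            ]
        )
    )
    if n_uninformative == len(starts):
        raise EstimationError("no informative matched sets")

    beta = np.zeros(X.shape[1])
    loglik, scores, hess = conditional_loglik_parts(beta, X, case, starts, w)
    converged = False
    for _ in range(max_iter):
        grad = scores.sum(axis=0)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as err:
            raise EstimationError(f"singular information matrix: {err}") from err
        # Step-halving line search on the log-likelihood.
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            new_loglik, new_scores, new_hess = conditional_loglik_parts(
                cand, X, case, starts, w
            )
            if new_loglik >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, scores, hess = cand, new_scores, new_hess
        if (
            np.max(np.abs(scores.sum(axis=0))) < 1e-7
            and abs(new_loglik - loglik) <= tol * (abs(loglik) + 1e-12)
        ):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    flagged = None
    if not converged:
        flagged = "no convergence"
    elif np.max(np.abs(beta)) > 15:
        flagged = "possible complete separation (|coefficient| > 15)"
    if flagged:
        logger.warning("conditional logistic fit flagged: %s", flagged)

    info = -hess
    bread = np.linalg.inv(info)
    meat = scores.T @ scores
    sandwich = bread @ meat @ bread
    coef = pd.Series(beta, index=names)
    est = EffectEstimate(
        log_hr=float(coef.iloc[0]),
        se=float(np.sqrt(sandwich[0, 0])),
        estimator="ncc-clogit" if weights is None else "ncc-clogit-iptw",
        n=len(starts),
        coefficients=coef,
        model_se=float(np.sqrt(bread[0, 0])),
        converged=converged,
        flagged=flagged,
        diagnostics={
            "loglik": loglik,
            "n_uninformative_sets": n_uninformative,
            "dropped_covariates": dropped,
            "max_abs_score": float(np.max(np.abs(scores.sum(axis=0)))),
            "sandwich_cov": sandwich,
            "model_cov": bread,
        },
    )
    return est


def split_counting_process(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counting-process rows split at the exposure switch day.

    Unexposed persons get one row ``[0, followup+1)``; exposed persons two
    rows split at the switch day (a single exposed row when the switch is
    at day 0).  The event flag sits on the final row.
    """
    switch = cohort["exposure_switch_day"].to_numpy(dtype=float)
    followup = cohort["followup_days"].to_numpy(dtype=float)
    if np.any(switch[~np.isnan(switch)] > followup[~np.isnan(switch)]):
        raise ValueError("exposure_switch_day after follow-up end; cohort "
                         "assembly should have truncated it")
    stop = followup + 1.0
    has_split = ~np.isnan(switch) & (switch > 0)
    base_cols = [
        c
        for c in cohort.columns
        if c not in ("followup_days", "event", "exposure_switch_day")
    ]

    first = cohort[base_cols].copy()
    first["start"] = 0.0
    first["stop"] = np.where(has_split, switch, stop)
    first["exposed"] = (~np.isnan(switch)) & (switch <= 0)
    first["event"] = np.where(has_split, False, cohort["event"])

    second = cohort.loc[has_split, base_cols].copy()
    second["start"] = switch[has_split]
    second["stop"] = stop[has_split]
    second["exposed"] = True
    second["event"] = cohort.loc[has_split, "event"]

    rows = pd.concat([first, second], ignore_index=True)
    rows = rows.sort_values(["person_id", "start"], kind="stable").reset_index(
        drop=True
    )
    rows["exposed"] = rows["exposed"].astype(bool)
    rows["event"] = rows["event"].astype(bool)
    return rows


def _encode_numeric(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    out = df.copy()
    names: list[str] = []
    for cov in covariates:
        if np.issubdtype(out[cov].dtype, np.number) or out[cov].dtype == bool:
            out[cov] = out[cov].astype(float)
            names.append(cov)
        else:
            dummies = pd.get_dummies(out[cov], prefix=cov, drop_first=True)
            for c in dummies.columns:
                out[c] = dummies[c].astype(float)
                names.append(c)
    return out, names


def fit_time_varying_cox(
    rows: pd.DataFrame,
    adjust: Sequence[str] = ("age_at_index", "sex"),
    strata: Sequence[str] = ("income_quintile", "cci_category", "calendar_period"),
) -> EffectEstimate:
    """Stratified Cox model with time-varying exposure (Efron ties)."""
    if not rows["event"].any():
        raise EstimationError("no events in counting-process data")
    df, adj_names = _encode_numeric(rows, adjust)
    cols = ["person_id", "start", "stop", "event", "exposed", *adj_names]
    strata = [s for s in strata if s in df.columns]
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    ctv.fit(
        df[cols + list(strata)],
        id_col="person_id",
        event_col="event",
        start_col="start",
        stop_col="stop",
        strata=list(strata) or None,
        show_progress=False,
    )
    coef = ctv.params_
    se = ctv.standard_errors_
    return EffectEstimate(
        log_hr=float(coef["exposed"]),
        se=float(se["exposed"]),
        estimator="cox-tv",
        n=int(rows["person_id"].nunique()),
        coefficients=coef,
        model_se=float(se["exposed"]),
        model=ctv,
        fit_data=df[cols + list(strata)],
    )


def fit_naive_cox(
    cohort: pd.DataFrame,
    adjust: Sequence[str] = ("age_at_index", "sex"),
) -> EffectEstimate:
    """Deliberately naive time-fixed "ever exposed" Cox fit.

    Classifies all follow-up of ever-exposed persons as exposed, including
    the pre-switch span during which they could not have been exposed cases
    -- the textbook immortal time bias, biased toward apparent benefit.
    """
    df = cohort.copy()
    df["ever_exposed"] = df["exposure_switch_day"].notna().astype(float)
    df["duration"] = df["followup_days"].astype(float) + 1.0
    df, adj_names = _encode_numeric(df, adjust)
    cph = CoxPHFitter()
    cph.fit(
        df[["duration", "event", "ever_exposed", *adj_names]],
        duration_col="duration",
        event_col="event",
    )
    return EffectEstimate(
        log_hr=float(cph.params_["ever_exposed"]),
        se=float(cph.standard_errors_["ever_exposed"]),
        estimator="cox-naive-ever-exposed",
        n=len(cohort),
        coefficients=cph.params_,
        model=cph,
        fit_data=df,
    )


def km_logrank(
    df: pd.DataFrame,
    time_col: str = "followup_days",
    event_col: str = "event",
    group_col: str = "exposed",
):
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns ``(curves, test)`` where ``curves`` maps group label to the
    fitted survival function (DataFrame) and ``test`` is the lifelines
    result (None with fewer than two groups).
    """
    if df.empty:
        raise ValueError("empty data")
    curves: dict[Any, pd.DataFrame] = {}
    groups = sorted(df[group_col].unique(), key=str)
    for g in groups:
        sub = df[df[group_col] == g]
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub[time_col], sub[event_col])
        curves[g] = kmf.survival_function_
    test = None
    if len(groups) == 2:
        a = df[df[group_col] == groups[0]]
        b = df[df[group_col] == groups[1]]
        test = logrank_test(
            a[time_col], b[time_col], a[event_col], b[event_col]
        )
    return curves, test


@dataclass
class MantelByarResult:
    statistic: float
    p_value: float
    observed_exposed_deaths: float
    expected_exposed_deaths: float


def mantel_byar_test(cohort: pd.DataFrame) -> MantelByarResult:
    """Log-rank test with time-varying group membership (Mantel-Byar).

    The classical log-rank on "ever exposed" groups is anticonservative
    under the null because group membership is conditioned on surviving
    long enough to accrue exposure (immortal time).  The Mantel-Byar
    variant classifies each at-risk person by their exposure status at the
    event time, which restores calibration; it equals the score test of
    the time-varying Cox model at beta = 0.
    """
    followup = cohort["followup_days"].to_numpy()
    event = cohort["event"].to_numpy(dtype=bool)
    switch = cohort["exposure_switch_day"].to_numpy(dtype=float)
    if not event.any():
        raise EstimationError("no events")
    u = v = obs = expd = 0.0
    for d in np.unique(followup[event]):
        at_risk = followup >= d
        exposed = at_risk & ~np.isnan(switch) & (switch <= d)
        n = at_risk.sum()
        n1 = exposed.sum()
        deaths = event & (followup == d)
        d_tot = deaths.sum()
        d1 = (deaths & exposed).sum()
        e1 = d_tot * n1 / n
        u += d1 - e1
        obs += d1
        expd += e1
        if n > 1:
            v += d_tot * (n1 / n) * (1 - n1 / n) * (n - d_tot) / (n - 1)
    if v == 0:
        raise EstimationError("no between-group variance at any event time")
    from scipy.stats import chi2

    stat = u * u / v
    return MantelByarResult(
        statistic=float(stat),
        p_value=float(chi2.sf(stat, df=1)),
        observed_exposed_deaths=float(obs),
        expected_exposed_deaths=float(expd),
    )


def ph_check(fit: EffectEstimate) -> pd.Series:
    """Proportional-hazards check, per covariate p-values.

    For a plain Cox fit this is the scaled-Schoenfeld-residual association
    test (rank time transform).  For the counting-process (time-varying)
    fit, where Schoenfeld-based machinery is unavailable, each covariate is
    tested through the Wald p-value of an added covariate x log(stop)
    interaction.
    """
    if fit.model is None:
        raise EstimationError("fit carries no underlying model")
    if isinstance(fit.model, CoxPHFitter):
        if not fit.fit_data[fit.model.event_col].any():
            raise EstimationError("no events")
        res = proportional_hazard_test(fit.model, fit.fit_data, time_transform="rank")
        pvals = res.summary["p"]
        if isinstance(pvals.index, pd.MultiIndex):
            pvals = pvals.droplevel(-1)
        return pvals.astype(float)
    if isinstance(fit.model, CoxTimeVaryingFitter):
        base = fit.fit_data
        covs = [c for c in fit.coefficients.index]
        strata = list(getattr(fit.model, "strata", None) or [])
        pvals = {}
        for cov in covs:
            df = base.copy()
            df["_tt"] = df[cov] * np.log(df["stop"])
            ctv = CoxTimeVaryingFitter(penalizer=0.0)
            ctv.fit(
                df,
                id_col="person_id",
                event_col="event",
                start_col="start",
                stop_col="stop",
                strata=strata or None,
                show_progress=False,
            )
            pvals[cov] = float(ctv.summary.loc["_tt", "p"])
        return pd.Series(pvals)
    raise EstimationError(f"unsupported model type {type(fit.model)!r}")
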