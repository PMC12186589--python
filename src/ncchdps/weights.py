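"""Propensity scores, stabilized truncated IPT weights, and balance
diagnostics on the nested case-control sample (hdPS steps vi-vii support).

The propensity score is the probability of (time-matched) exposure given
investigator covariates plus the selected high-dimensional recurrence
covariates, estimated on the NCC sample where the exposure is time-fixed.
Stabilized weights use the marginal exposure prevalence as numerator and
are truncated at the 99th percentile (upper tail only).  Balance is read
off standardized mean differences in the weighted pseudo-population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .config import PSModelSpec
from .models import EstimationError, _design_matrix

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """Per-row stabilized IPT weights, before and after truncation."""

    scores: np.ndarray
    stabilized: np.ndarray
    truncated: np.ndarray
    truncation_quantile: float
    cap: float

    def summary(self, which: str = "truncated") -> dict[str, float]:
        w = getattr(self, which)
        q1, med, q3 = np.quantile(w, [0.25, 0.5, 0.75])
        return {
            "min": float(w.min()),
            "q1": float(q1),
            "median": float(med),
            "mean": float(w.mean()),
            "q3": float(q3),
            "max": float(w.max()),
        }


def estimate_ps(
    data: pd.DataFrame,
    spec: PSModelSpec,
    hd_covariates: Sequence[str] = (),
    exposure_col: str = "exposed",
) -> np.ndarray:
    """Propensity scores on the NCC sample.

    ``lasso-logistic`` fits an L1-penalized logistic regression with the
    regularization strength chosen by seeded 5-fold cross-validation;
    ``gradient-boosted-trees`` fits an XGBoost classifier with the spec's
    hyperparameters and a fixed seed.  Scores are clipped away from
    {0, 1} by ``spec.clip_epsilon``.
    """
    exposure = data[exposure_col].to_numpy(dtype=int)
    if exposure.all() or not exposure.any():
        raise EstimationError("single exposure level; propensity score "
                              "model not identifiable")
    covs = [*spec.investigator_covariates, *hd_covariates]
    X, names = _design_matrix(data, covs)
    if spec.method == "lasso-logistic":
        scaler = StandardScaler()
        Z = scaler.fit_transform(X)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=spec.seed)
        model = LogisticRegressionCV(
            Cs=np.logspace(-3, 2, 10),
            penalty="l1",
            solver="liblinear",
            cv=cv,
            scoring="neg_log_loss",
            max_iter=2000,
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            # scikit-learn 1.9 emits transitional FutureWarnings about the
            # upcoming l1_ratios API; the l1 fit itself is unaffected.
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(Z, exposure)
        scores = model.predict_proba(Z)[:, 1]
    else:  # gradient-boosted-trees
        from xgboost import XGBClassifier

        params = {
            "n_estimators": 200,
            "max_depth": 3,
            "learning_rate": 0.1,
            "subsample": 0.9,
            "n_jobs": 1,
            **dict(spec.hyperparameters),
        }
        model = XGBClassifier(random_state=spec.seed, **params)
        model.fit(X, exposure)
        scores = model.predict_proba(X)[:, 1].astype(float)
    eps = spec.clip_epsilon
    return np.clip(scores, eps, 1.0 - eps)


def stabilized_weights(
    scores: np.ndarray,
    exposure: np.ndarray,
    truncation_quantile: float = 0.99,
) -> WeightVector:
    """Stabilized IPT weights truncated at the given upper quantile.

    Weight = p/score for exposed, (1-p)/(1-score) for unexposed, with the
    marginal exposure prevalence p as numerator; values above the
    ``truncation_quantile`` of the stabilized weights are capped at that
    quantile (the lower tail is untouched).
    """
    scores = np.asarray(scores, dtype=float)
    e = np.asarray(exposure, dtype=bool)
    if np.any((scores <= 0) | (scores >= 1)):
        raise ValueError("scores must lie strictly inside (0, 1)")
    p = e.mean()
    w = np.where(e, p / scores, (1.0 - p) / (1.0 - scores))
    cap = float(np.quantile(w, truncation_quantile))
    return WeightVector(
        scores=scores,
        stabilized=w,
        truncated=np.minimum(w, cap),
        truncation_quantile=truncation_quantile,
        cap=cap,
    )


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mean = np.average(x, weights=w)
    var = np.average((x - mean) ** 2, weights=w)
    return float(mean), float(var)


def compute_smd(
    values: pd.Series | np.ndarray,
    exposure: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Absolute standardized mean difference between exposure groups.

    ``|mean1 - mean0| / sqrt((var1 + var0) / 2)`` with weighted means and
    variances.  Categorical input is indicator-expanded and the maximum SMD
    over levels is reported.  Zero pooled variance with unequal means
    yields +inf (flagged by the caller's balance table).
    """
    e = np.asarray(exposure, dtype=bool)
    if weights is None:
        weights = np.ones(len(e))
    w = np.asarray(weights, dtype=float)
    x = values if isinstance(values, pd.Series) else pd.Series(np.asarray(values))
    if not (np.issubdtype(x.dtype, np.number) or x.dtype == bool):
        levels = pd.get_dummies(x)
        return max(
            compute_smd(levels[c].astype(float), e, w) for c in levels.columns
        )
    xv = x.to_numpy(dtype=float)
    m1, v1 = _weighted_mean_var(xv[e], w[e])
    m0, v0 = _weighted_mean_var(xv[~e], w[~e])
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        return 0.0 if m1 == m0 else float("inf")
    return float(abs(m1 - m0) / denom)


def balance_table(
    data: pd.DataFrame,
    covariates: Sequence[str],
    exposure_col: str = "exposed",
    weights: np.ndarray | None = None,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """SMD per covariate in the (weighted) sample, with a balanced flag
    (SMD <= threshold passes; equality is balanced)."""
    e = data[exposure_col].to_numpy(dtype=bool)
    rows = []
    for cov in covariates:
        smd = compute_smd(data[cov], e, weights)
        if np.isinf(smd):
            logger.warning("covariate %s: zero pooled variance with unequal "
                           "means; SMD infinite", cov)
        rows.append({"covariate": cov, "smd": smd, "balanced": smd <= threshold})
    return pd.DataFrame(rows, columns=["covariate", "smd", "balanced"])


def balance_gate(balance: pd.DataFrame, threshold: float = 0.2) -> list[str]:
    """Covariates exceeding the SMD threshold after weighting; these are
    re-adjusted in the outcome model."""
    return balance.loc[balance["smd"] > threshold, "covariate"].tolist()
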