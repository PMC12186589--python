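"""High-dimensional propensity score engine: proxy-code ingestion,
prevalence filtering, recurrence expansion, and covariate prioritization.

Steps implemented (the seven-step hdPS algorithm, steps i-v):

1. count each proxy code per person within the 1-year pre-index window,
   truncated to 3- or 4-digit granularity, with study-defining codes
   (comorbidity-index codes, the disease codes, treatment drug
   identification numbers) excluded;
2. keep the ``top_n`` most prevalent codes per data dimension;
3. expand each code into up to three binary recurrence covariates
   (recorded >= once / >= carrier median / >= carrier 75th percentile);
4. prioritize recurrence covariates for the survival outcome by
   cross-validated Cox-LASSO (|log-HR| at the CV-minimum lambda), by a
   random survival forest importance, or by the Bross bias multiplier;
5. select the top ``k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .config import ConfigError, DIMENSIONS, DimensionSpec

logger = logging.getLogger(__name__)


@dataclass
class RecurrenceMatrix:
    """Persons x binary recurrence covariates.

    ``data`` holds 0/1 integers with covariate names
    ``<dimension>_<code>_<once|med|q75>``; ``thresholds`` maps covariate
    name to the count threshold it encodes (including columns dropped as
    duplicates, so provenance is never lost).
    """

    data: pd.DataFrame
    thresholds: dict[str, float]
    dropped_duplicates: dict[str, str]


@dataclass(frozen=True)
class PriorityScore:
    covariate: str
    score: float
    rank: int
    method: str


@dataclass(frozen=True)
class BrossInputs:
    """Prevalence of a binary covariate among exposed (pc1) and unexposed
    (pc0), and its risk ratio with the outcome (rr_cd)."""

    pc1: float
    pc0: float
    rr_cd: float

    def __post_init__(self) -> None:
        if not (0 <= self.pc1 <= 1 and 0 <= self.pc0 <= 1):
            raise ValueError("pc1 and pc0 must be in [0, 1]")
        if self.rr_cd <= 0:
            raise ValueError("rr_cd must be > 0")


def _truncate_code(codes: pd.Series, dimension: str, granularity: int) -> pd.Series:
    """ICD-style codes truncate to 'XXX' (3-digit) or 'XXX.X' (4-digit);
    procedure and drug-identification codes are kept whole."""
    if dimension not in ("physician_icd", "hospital_icd"):
        return codes
    parts = codes.str.split(".", n=1)
    base = parts.str[0].str[:3]
    if granularity == 3:
        return base
    decimal = parts.str[1].fillna("").str[:1]
    return np.where(decimal != "", base + "." + decimal, base)


def count_codes(
    code_events: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: DimensionSpec,
    window_days: int = 365,
) -> pd.DataFrame:
    """Per-person within-window counts of each code of one dimension.

    Returns a wide integer frame indexed by ``person_id`` (every cohort
    member, zeros included) with columns ``<dimension>_<code>``.
    """
    if spec.name not in DIMENSIONS:
        raise ConfigError(f"unknown dimension {spec.name!r}")
    persons = cohort["person_id"]
    index_date = pd.to_datetime(cohort["index_date"])
    empty = pd.DataFrame(index=pd.Index(persons, name="person_id"))
    ev = code_events[code_events["dimension"] == spec.name]
    if ev.empty:
        return empty
    idx_map = pd.Series(index_date.to_numpy(), index=persons.to_numpy())
    ev = ev[ev["person_id"].isin(idx_map.index)].copy()
    ev_idx = idx_map.reindex(ev["person_id"]).to_numpy()
    dates = pd.to_datetime(ev["event_date"]).to_numpy()
    in_window = (dates < ev_idx) & (
        dates >= ev_idx - np.timedelta64(window_days, "D")
    )
    ev = ev[in_window]
    if ev.empty:
        return empty
    code = pd.Series(
        _truncate_code(ev["code"].astype(str), spec.name, spec.code_granularity),
        index=ev.index,
    )
    keep = ~code.isin(spec.excluded_codes)
    ev = ev.assign(code_t=code)[keep]
    if ev.empty:
        return empty
    counts = (
        ev.groupby(["person_id", "code_t"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(persons.to_numpy(), fill_value=0)
    )
    counts.index.name = "person_id"
    counts.columns = [f"{spec.name}_{c}" for c in counts.columns]
    return counts.astype(int)


def prevalence_filter(counts: pd.DataFrame, top_n: int) -> list[str]:
    """Columns of the ``top_n`` most prevalent codes per dimension.

    Prevalence = number of persons with count >= 1 ("most prevalent", by
    carrier count descending), ties broken lexicographically by name.
    Column order of the result is deterministic (rank, then name).
    """
    if counts.shape[1] == 0:
        return []
    carriers = (counts >= 1).sum(axis=0)
    by_dim: dict[str, list[tuple[int, str]]] = {}
    for name, k in carriers.items():
        dim = next(d for d in DIMENSIONS if name.startswith(d + "_"))
        by_dim.setdefault(dim, []).append((int(k), name))
    retained: list[str] = []
    for dim in sorted(by_dim):
        ranked = sorted(by_dim[dim], key=lambda t: (-t[0], t[1]))
        retained.extend(name for _, name in ranked[:top_n])
    return retained


def build_recurrence(counts: pd.DataFrame) -> RecurrenceMatrix:
    """Expand code counts into binary recurrence covariates.

    Per code, thresholds are 1, the median, and the 75th percentile of
    counts among carriers (count >= 1; linear-interpolation quantiles),
    applied as ``count >= threshold``.  Columns identical to an
    already-kept column are dropped; their thresholds stay recorded.
    """
    data: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    dropped: dict[str, str] = {}
    seen: dict[bytes, str] = {}
    for col in counts.columns:
        x = counts[col].to_numpy()
        carriers = x[x >= 1]
        if carriers.size == 0:
            logger.info("code %s has zero carriers; skipped", col)
            continue
        med = float(np.quantile(carriers, 0.5))
        q75 = float(np.quantile(carriers, 0.75))
        for suffix, thr in (("once", 1.0), ("med", med), ("q75", q75)):
            name = f"{col}_{suffix}"
            vec = (x >= thr).astype(np.int8)
            thresholds[name] = thr
            key = vec.tobytes()
            if key in seen:
                dropped[name] = seen[key]
            else:
                seen[key] = name
                data[name] = vec
    frame = pd.DataFrame(data, index=counts.index, dtype=np.int8)
    return RecurrenceMatrix(data=frame, thresholds=thresholds, dropped_duplicates=dropped)


# ---------------------------------------------------------------------------
# prioritizers
# ---------------------------------------------------------------------------


def _rank_scores(scores: pd.Series, k: int, method: str) -> list[PriorityScore]:
    """Rank descending by score, ties lexicographic; return the top k."""
    order = sorted(scores.items(), key=lambda t: (-t[1], t[0]))
    return [
        PriorityScore(covariate=name, score=float(s), rank=r + 1, method=method)
        for r, (name, s) in enumerate(order[:k])
    ]


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    nunique = X.nunique(axis=0)
    constant = nunique[nunique <= 1].index
    if len(constant):
        logger.info("dropping %d constant covariate(s)", len(constant))
    return X.drop(columns=constant)


def _breslow_loglik(time: np.ndarray, event: np.ndarray, eta: np.ndarray) -> float:
    """Breslow partial log-likelihood, used to score CV folds."""
    order = np.argsort(-time, kind="stable")
    t, e, h = time[order], event[order], eta[order]
    m = h.max()
    log_risk = np.log(np.cumsum(np.exp(h - m))) + m
    # Ties: all deaths at a time share the full risk set at that time.
    last_at_time = np.r_[t[1:] != t[:-1], True]
    idx = np.arange(len(t))
    grp = np.maximum.accumulate(np.where(last_at_time, idx, -1)[::-1])[::-1]
    return float(np.sum(e * (h - log_risk[grp])))


def _event_stratified_folds(
    event: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Fold labels from a seeded permutation, separately for events and
    censored rows, so every fold holds events."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(event), dtype=int)
    for mask in (event.astype(bool), ~event.astype(bool)):
        idx = np.flatnonzero(mask)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def prioritize_cox_lasso(
    recurrence: RecurrenceMatrix | pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    k: int = 200,
    folds: int = 5,
    seed: int = 0,
    n_alphas: int = 40,
) -> list[PriorityScore]:
    """Rank recurrence covariates by |log-HR| from cross-validated Cox-LASSO.

    An L1-penalized Cox model is fitted over a lambda path on internally
    standardized columns; lambda is chosen by ``folds``-fold event-stratified
    cross-validation maximizing the held-out partial log-likelihood (the
    minimum-prediction-error rule).  Coefficients are reported on the
    original 0/1 coding; zero-coefficient covariates rank after nonzero
    ones.
    """
    X = recurrence.data if isinstance(recurrence, RecurrenceMatrix) else recurrence
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for Cox-LASSO prioritization")
    X = _drop_constant(X)
    if X.shape[1] == 0 or k <= 0:
        return []
    mu = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=0).to_numpy()
    Z = (X.to_numpy(dtype=float) - mu) / sd
    y = Surv.from_arrays(event, time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01, normalize=False
    )
    path.fit(Z, y)
    alphas = path.alphas_

    fold = _event_stratified_folds(event, folds, seed)
    cv_loglik = np.zeros(len(alphas))
    for f in range(folds):
        train, test = fold != f, fold == f
        m = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, normalize=False
        )
        m.fit(Z[train], Surv.from_arrays(event[train], time[train]))
        coefs = m.coef_  # p x len(m.alphas_); the path may stop early
        fitted = np.asarray(m.alphas_)
        for a, alpha in enumerate(alphas):
            col = int(np.argmin(np.abs(np.log(fitted) - np.log(alpha))))
            eta = Z[test] @ coefs[:, col]
            cv_loglik[a] += _breslow_loglik(time[test], event[test], eta)
    best = int(np.argmax(cv_loglik))
    coef_std = path.coef_[:, best]
    coef = coef_std / sd  # back to the original 0/1 coding
    scores = pd.Series(np.abs(coef), index=X.columns)
    ranked = _rank_scores(scores, min(k, len(scores)), "cox-lasso")
    n_nonzero = int((scores > 0).sum())
    logger.info(
        "cox-lasso: CV-min lambda %.5g with %d nonzero of %d covariates",
        alphas[best], n_nonzero, len(scores),
    )
    return ranked


def prioritize_rsf(
    recurrence: RecurrenceMatrix | pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    k: int = 200,
    n_trees: int = 200,
    seed: int = 0,
    n_repeats: int = 3,
    max_score_rows: int = 600,
) -> list[PriorityScore]:
    """Rank covariates by seeded permutation importance of a random
    survival forest (concordance loss when the covariate is shuffled).

    Importance scoring subsamples to at most ``max_score_rows`` rows (the
    concordance index is quadratic in rows); deterministic under a fixed
    seed.
    """
    X = recurrence.data if isinstance(recurrence, RecurrenceMatrix) else recurrence
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for survival-forest prioritization")
    X = _drop_constant(X)
    if X.shape[1] == 0 or k <= 0:
        return []
    Xa = X.to_numpy(dtype=float)
    y = Surv.from_arrays(event, time)
    rsf = RandomSurvivalForest(
        n_estimators=n_trees,
        min_samples_leaf=15,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    rsf.fit(Xa, y)

    rng = np.random.default_rng(seed)
    if len(Xa) > max_score_rows:
        sub = rng.choice(len(Xa), size=max_score_rows, replace=False)
    else:
        sub = np.arange(len(Xa))
    Xs, ys = Xa[sub], y[sub]
    base = rsf.score(Xs, ys)
    imp = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = Xs.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xs)), j]
            drops.append(base - rsf.score(Xp, ys))
        imp[j] = np.mean(drops)
    scores = pd.Series(np.maximum(imp, 0.0), index=X.columns)
    return _rank_scores(scores, min(k, len(scores)), "rsf")


def bross_multiplier(b: BrossInputs) -> float:
    """Multiplicative confounding bias of a binary covariate:
    ``[pc1 (rr_cd - 1) + 1] / [pc0 (rr_cd - 1) + 1]``."""
    return (b.pc1 * (b.rr_cd - 1.0) + 1.0) / (b.pc0 * (b.rr_cd - 1.0) + 1.0)


def prioritize_bross(
    recurrence: RecurrenceMatrix | pd.DataFrame,
    exposure: np.ndarray,
    outcome: np.ndarray,
    k: int = 200,
) -> list[PriorityScore]:
    """Rank covariates by |log Bross multiplier| with plug-in estimates.

    ``pc1``/``pc0`` are covariate prevalences among exposed/unexposed;
    ``rr_cd`` is the outcome risk ratio across covariate levels.  A 0.5
    continuity correction is applied to zero cells of the risk-ratio
    estimate (logged).
    """
    X = recurrence.data if isinstance(recurrence, RecurrenceMatrix) else recurrence
    e = np.asarray(exposure, dtype=bool)
    d = np.asarray(outcome, dtype=bool)
    if e.all() or not e.any():
        raise ValueError("both exposure levels required for Bross prioritization")
    n1, n0 = e.sum(), (~e).sum()
    scores = {}
    n_corrected = 0
    for col in X.columns:
        c = X[col].to_numpy(dtype=bool)
        pc1 = c[e].sum() / n1
        pc0 = c[~e].sum() / n0
        a, nc1 = d[c].sum(), c.sum()
        bcell, nc0 = d[~c].sum(), (~c).sum()
        if min(a, bcell, nc1 - a, nc0 - bcell) == 0 or nc1 == 0 or nc0 == 0:
            n_corrected += 1
            rr = ((a + 0.5) / (nc1 + 1.0)) / ((bcell + 0.5) / (nc0 + 1.0))
        else:
            rr = (a / nc1) / (bcell / nc0)
        mult = bross_multiplier(BrossInputs(pc1=pc1, pc0=pc0, rr_cd=rr))
        scores[col] = abs(np.log(mult))
    if n_corrected:
        logger.info("bross: continuity correction applied to %d covariate(s)",
                    n_corrected)
    return _rank_scores(pd.Series(scores), min(k, len(scores)), "bross")


def priorities_frame(scores: list[PriorityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.covariate, s.method, s.score, s.rank) for s in scores],
        columns=["covariate", "method", "score", "rank"],
    )
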