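"""Analytic-cohort construction from raw claims-style tables.

Turns the persons / dispensations / code-events tables into one row per
eligible person with: index date, age, sex, income quintile, comorbidity
category, calendar period, follow-up days, death indicator, and the
cumulative-use exposure switch day (days since index; NaN if the person
never reached the class-specific threshold within follow-up).

Time conventions: day 0 is the index date; intervals are half-open
``[start, end)``; follow-up and switch days are integer day counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CciWeightMap, ExposureRule
from .simulate import RawTables

logger = logging.getLogger(__name__)

CALENDAR_PERIODS = ("1996-1999", "2000-2005", "2006-2011", "2012-2017")

COHORT_COLUMNS = [
    "person_id",
    "index_date",
    "age_at_index",
    "sex",
    "income_quintile",
    "cci_score",
    "cci_category",
    "calendar_period",
    "followup_days",
    "event",
    "exposure_switch_day",
]


def derive_index_date(
    study_start,
    birth_date,
    first_ms_evidence=None,
    first_dmd=None,
) -> pd.Timestamp:
    """Index date = the most recent clinically relevant event.

    Candidates: first evidence of the disease, first disease-modifying-drug
    dispensation, the person's 18th birthday, and the study start; the
    latest defined candidate wins.
    """
    birth = pd.Timestamp(birth_date)
    candidates = [pd.Timestamp(study_start), birth + pd.DateOffset(years=18)]
    for cand in (first_ms_evidence, first_dmd):
        if cand is not None and not pd.isna(cand):
            candidates.append(pd.Timestamp(cand))
    return max(candidates)


def _coverage_intervals(
    days: np.ndarray, supplies: np.ndarray
) -> list[tuple[float, float]]:
    """Queue same-class supplies end-to-end: a dispensation arriving while
    coverage is running starts when the running supply is exhausted."""
    order = np.argsort(days, kind="stable")
    intervals: list[tuple[float, float]] = []
    cur_end = -np.inf
    for i in order:
        start = max(float(days[i]), cur_end)
        end = start + float(supplies[i])
        intervals.append((start, end))
        cur_end = end
    return intervals


def accrue_exposure(
    dispensations: pd.DataFrame,
    rule: ExposureRule,
    index_date=None,
) -> float:
    """First day (since index) on which cumulative use reaches the threshold.

    ``dispensations`` holds one person's rows with columns ``drug_class``,
    ``days_supplied`` and either ``dispense_day`` (days since index) or
    ``dispense_date`` plus an ``index_date`` argument.  Per drug class,
    supplies are queued end-to-end into coverage intervals; covered days
    before the index do not count.  In the default ``cumulative`` mode
    supplied days accumulate across the person's whole history; in
    ``episode`` mode the counter restarts whenever the gap between coverage
    runs exceeds ``rule.max_gap`` days.  Returns NaN if no class threshold
    is ever reached.
    """
    if len(dispensations) == 0:
        return np.nan
    if "dispense_day" in dispensations.columns:
        days = dispensations["dispense_day"].to_numpy(dtype=float)
    else:
        if index_date is None:
            raise ValueError("index_date required when dispense_day is absent")
        days = (
            pd.to_datetime(dispensations["dispense_date"]) - pd.Timestamp(index_date)
        ).dt.days.to_numpy(dtype=float)
    supplies = dispensations["days_supplied"].to_numpy(dtype=float)
    classes = dispensations["drug_class"].to_numpy()

    best = np.nan
    for cls in np.unique(classes):
        mask = classes == cls
        day = _accrue_one_class(
            days[mask], supplies[mask], rule.threshold_for(cls), rule
        )
        if not np.isnan(day) and (np.isnan(best) or day < best):
            best = day
    return best


def _accrue_one_class(
    days: np.ndarray, supplies: np.ndarray, threshold: int, rule: ExposureRule
) -> float:
    intervals = _coverage_intervals(days, supplies)
    cum = 0.0
    prev_end: float | None = None
    for start, end in intervals:
        if rule.mode == "episode" and prev_end is not None:
            if start - prev_end > rule.max_gap:
                cum = 0.0
        prev_end = end
        a, b = max(start, 0.0), max(end, 0.0)  # pre-index days never count
        length = b - a
        if length <= 0:
            continue
        if cum + length >= threshold:
            return a + (threshold - cum) - 1.0
        cum += length
    return np.nan


@dataclass
class CciResult:
    score: int
    category: str


def _truncate_icd(codes: pd.Series) -> pd.Series:
    return codes.str.split(".", n=1).str[0].str[:3]


def compute_cci(
    code_events: pd.DataFrame,
    weights: CciWeightMap,
    index_date=None,
    window_days: int = 365,
) -> CciResult:
    """Comorbidity score for one person from diagnosis events.

    Counts distinct condition groups (not occurrences) whose codes appear in
    the 1-year pre-index window, summing group weights; excluded codes are
    ignored.  Category buckets the score as {0, 1, 2, 3+}.
    """
    events = code_events
    if index_date is not None and len(events):
        dates = pd.to_datetime(events["event_date"])
        idx = pd.Timestamp(index_date)
        events = events[(dates >= idx - pd.Timedelta(days=window_days)) & (dates < idx)]
    if "dimension" in events.columns and len(events):
        events = events[events["dimension"].isin(["physician_icd", "hospital_icd"])]
    score = 0
    if len(events):
        codes = _truncate_icd(events["code"].astype(str))
        codes = codes[~codes.isin(weights.excluded_codes)]
        seen_groups: dict[str, int] = {}
        for code in codes.unique():
            if code in weights.weights:
                group, weight = weights.weights[code]
                seen_groups[group] = max(seen_groups.get(group, 0), weight)
        score = int(sum(seen_groups.values()))
    return CciResult(score=score, category=_cci_category(score))


def _cci_category(score) -> str:
    return str(int(min(score, 3))) + ("+" if score >= 3 else "")


def calendar_period(year: int) -> str:
    if year <= 1999:
        return CALENDAR_PERIODS[0]
    if year <= 2005:
        return CALENDAR_PERIODS[1]
    if year <= 2011:
        return CALENDAR_PERIODS[2]
    return CALENDAR_PERIODS[3]


@dataclass
class CohortBuildResult:
    cohort: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["person_id", "reason"])
    )


def assemble_cohort(
    raw: RawTables,
    rule: ExposureRule | None = None,
    weights: CciWeightMap | None = None,
    study_end: str = "2017-12-31",
) -> CohortBuildResult:
    """Build the analytic cohort from raw tables.

    The persons table's ``cohort_entry_date`` is taken as the index date
    (the simulator defines it that way; for raw registry data derive it
    first with :func:`derive_index_date`).  Follow-up runs from index to the
    earliest of death, administrative censoring, and ``study_end``; the
    exposure switch day is recomputed from dispensations and truncated to
    NaN when it falls after follow-up ends.
    """
    rule = rule or ExposureRule()
    weights = weights or CciWeightMap()
    persons = raw.persons
    if persons.empty:
        return CohortBuildResult(cohort=pd.DataFrame(columns=COHORT_COLUMNS))

    index_date = pd.to_datetime(persons["cohort_entry_date"])
    end_date = pd.to_datetime(persons["end_date"])
    birth = pd.to_datetime(persons["birth_date"])
    study_end_ts = pd.Timestamp(study_end)

    bad = end_date < index_date
    exclusions = pd.DataFrame(
        {
            "person_id": persons.loc[bad, "person_id"],
            "reason": "end_date before index_date",
        }
    )
    if bad.any():
        logger.info("excluded %d person(s): end_date before index_date", bad.sum())

    keep = ~bad
    persons = persons[keep].reset_index(drop=True)
    index_date = index_date[keep].reset_index(drop=True)
    end_date = end_date[keep].reset_index(drop=True)
    birth = birth[keep].reset_index(drop=True)

    clamped_end = end_date.clip(upper=study_end_ts)
    followup = (clamped_end - index_date).dt.days
    event = persons["died"].to_numpy(dtype=bool) & (end_date <= study_end_ts).to_numpy()

    cci = _cci_all_persons(raw.code_events, persons, index_date, weights)
    switch = _accrue_all_persons(raw.dispensations, persons, index_date, rule)
    switch = np.where(switch <= followup.to_numpy(), switch, np.nan)

    cohort = pd.DataFrame(
        {
            "person_id": persons["person_id"],
            "index_date": index_date.dt.strftime("%Y-%m-%d"),
            "age_at_index": (index_date - birth).dt.days / 365.25,
            "sex": persons["sex"],
            "income_quintile": persons["income_quintile"].astype(int),
            "cci_score": cci["score"].to_numpy(),
            "cci_category": cci["category"].to_numpy(),
            "calendar_period": index_date.dt.year.map(calendar_period),
            "followup_days": followup.astype(int),
            "event": event,
            "exposure_switch_day": switch,
        }
    )
    return CohortBuildResult(cohort=cohort, exclusions=exclusions)


def _cci_all_persons(
    code_events: pd.DataFrame,
    persons: pd.DataFrame,
    index_date: pd.Series,
    weights: CciWeightMap,
) -> pd.DataFrame:
    """Vectorised distinct-condition-group comorbidity score per person."""
    out = pd.DataFrame(
        {"score": np.zeros(len(persons), dtype=int), "category": "0"},
        index=persons["person_id"],
    )
    if code_events.empty:
        out["category"] = out["score"].map(_cci_category)
        return out
    ev = code_events[
        code_events["dimension"].isin(["physician_icd", "hospital_icd"])
    ].copy()
    idx_map = pd.Series(index_date.to_numpy(), index=persons["person_id"])
    ev = ev[ev["person_id"].isin(idx_map.index)]
    if ev.empty:
        out["category"] = out["score"].map(_cci_category)
        return out
    ev_idx = idx_map.reindex(ev["person_id"]).to_numpy()
    dates = pd.to_datetime(ev["event_date"]).to_numpy()
    window = (dates < ev_idx) & (dates >= ev_idx - np.timedelta64(365, "D"))
    ev = ev[window]
    codes = _truncate_icd(ev["code"].astype(str))
    ev = ev.assign(code3=codes)[~codes.isin(weights.excluded_codes)]
    wmap = pd.DataFrame(
        [(c, g, w) for c, (g, w) in weights.weights.items()],
        columns=["code3", "group", "weight"],
    )
    hits = ev.merge(wmap, on="code3")[["person_id", "group", "weight"]]
    if hits.empty:
        out["category"] = out["score"].map(_cci_category)
        return out
    per_group = hits.groupby(["person_id", "group"])["weight"].max()
    scores = per_group.groupby("person_id").sum()
    out.loc[scores.index, "score"] = scores.astype(int)
    out["category"] = out["score"].map(_cci_category)
    return out


def _accrue_all_persons(
    dispensations: pd.DataFrame,
    persons: pd.DataFrame,
    index_date: pd.Series,
    rule: ExposureRule,
) -> np.ndarray:
    switch = np.full(len(persons), np.nan)
    if dispensations.empty:
        return switch
    idx_map = pd.Series(index_date.to_numpy(), index=persons["person_id"])
    pos = pd.Series(np.arange(len(persons)), index=persons["person_id"])
    disp = dispensations[dispensations["person_id"].isin(idx_map.index)].copy()
    disp["dispense_day"] = (
        pd.to_datetime(disp["dispense_date"]).to_numpy()
        - idx_map.reindex(disp["person_id"]).to_numpy()
    ) / np.timedelta64(1, "D")
    for pid, grp in disp.groupby("person_id", sort=False):
        switch[pos[pid]] = accrue_exposure(grp, rule)
    return switch
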