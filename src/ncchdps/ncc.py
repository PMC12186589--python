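"""Nested case-control sampling with incidence density risk sets.

Each death (case) at day ``d`` is matched to up to ``m`` controls drawn
uniformly without replacement from the persons still at risk at ``d``
(follow-up >= d, not dying at d), restricted to the same matching key
(income quintile, comorbidity category, calendar period).  A person can
serve as a control in several sets and later become a case; sampling is
without replacement within a set and with replacement across sets.
Time-matched exposure (``exposed = switch day <= case's event day``) turns
the time-dependent exposure into a time-fixed one, which is what removes
immortal time bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATCHING_KEYS = ("income_quintile", "cci_category", "calendar_period")

NCC_COLUMNS = [
    "person_id",
    "set_id",
    "is_case",
    "event_day",
    "exposed",
    "age_at_index",
    "sex",
    "income_quintile",
    "cci_category",
    "calendar_period",
]


@dataclass
class MatchedSet:
    set_id: int
    case_id: str
    event_day: int
    control_ids: list[str]
    matching_key: tuple


@dataclass
class NCCDataset:
    """Long-format matched sets: one row per set member."""

    data: pd.DataFrame
    n_cases_dropped: int = 0
    m: int = 4
    sets: list[MatchedSet] = field(default_factory=list, repr=False)

    @property
    def n_cases(self) -> int:
        return int(self.data["is_case"].sum()) if len(self.data) else 0

    @property
    def n_controls(self) -> int:
        return int((~self.data["is_case"]).sum()) if len(self.data) else 0


def build_risk_sets(cohort: pd.DataFrame) -> dict[int, np.ndarray]:
    """Map each distinct event day to the ids of persons at risk then.

    At risk at day ``d`` means follow-up >= d; persons who died strictly
    before ``d`` have follow-up < d and drop out automatically, while cases
    dying at ``d`` are members of their own risk set.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    followup = cohort["followup_days"].to_numpy()
    ids = cohort["person_id"].to_numpy()
    event_days = np.unique(cohort.loc[cohort["event"], "followup_days"].to_numpy())
    return {int(d): ids[followup >= d] for d in event_days}


def sample_controls(
    case: pd.Series,
    risk_set_ids: np.ndarray,
    cohort: pd.DataFrame,
    m: int,
    rng: np.random.Generator,
) -> MatchedSet | None:
    """Draw up to ``m`` matched controls for one case; None when the pool
    is empty (the case is dropped and counted, not an error)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    event_day = int(case["followup_days"])
    sub = cohort[cohort["person_id"].isin(risk_set_ids)]
    alive = ~(sub["event"] & (sub["followup_days"] == event_day))
    key = tuple(case[k] for k in MATCHING_KEYS)
    same_key = np.ones(len(sub), dtype=bool)
    for k, v in zip(MATCHING_KEYS, key):
        same_key &= (sub[k] == v).to_numpy()
    pool = sub.loc[alive.to_numpy() & same_key, "person_id"].to_numpy()
    pool = pool[pool != case["person_id"]]
    if len(pool) == 0:
        return None
    chosen = rng.choice(np.sort(pool), size=min(m, len(pool)), replace=False)
    return MatchedSet(
        set_id=-1,
        case_id=case["person_id"],
        event_day=event_day,
        control_ids=list(chosen),
        matching_key=key,
    )


def assemble_ncc(
    cohort: pd.DataFrame,
    m: int = 4,
    seed: int | np.random.Generator = 0,
    keep_sets: bool = False,
) -> NCCDataset:
    """Sample all matched sets and assemble the analysis dataset.

    Cases are processed in (event day, person id) order so the output is
    deterministic given the seed.  Control pools are precomputed per
    matching stratum with searchsorted on follow-up, which makes sampling
    O(cases x pool) instead of O(cases x cohort).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base = cohort.reset_index(drop=True)
    followup = base["followup_days"].to_numpy()
    event = base["event"].to_numpy(dtype=bool)
    person_id = base["person_id"].to_numpy()
    switch = base["exposure_switch_day"].to_numpy(dtype=float)

    # Pre-group the cohort by matching stratum, sorted by follow-up, so the
    # at-risk pool at day d is a suffix found by searchsorted.
    key_codes = pd.MultiIndex.from_frame(base[list(MATCHING_KEYS)]).factorize()[0]
    strata: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for code in np.unique(key_codes):
        idx = np.flatnonzero(key_codes == code)
        order = np.lexsort((person_id[idx], followup[idx]))
        idx = idx[order]
        strata[code] = (idx, followup[idx], event[idx])

    case_order = np.flatnonzero(event)
    case_order = case_order[
        np.lexsort((person_id[case_order], followup[case_order]))
    ]

    member_idx: list[np.ndarray] = []
    member_case: list[np.ndarray] = []
    member_set: list[np.ndarray] = []
    member_day: list[np.ndarray] = []
    sets: list[MatchedSet] = []
    n_dropped = 0
    set_id = 0
    for ci in case_order:
        d = int(followup[ci])
        idx, fu, ev = strata[key_codes[ci]]
        lo = np.searchsorted(fu, d, side="left")
        cand = idx[lo:]
        alive = ~(ev[lo:] & (fu[lo:] == d))
        pool = cand[alive & (cand != ci)]
        if len(pool) == 0:
            n_dropped += 1
            continue
        chosen = rng.choice(pool, size=min(m, len(pool)), replace=False)
        k = len(chosen) + 1
        member_idx.append(np.concatenate(([ci], chosen)))
        member_case.append(np.r_[True, np.zeros(k - 1, dtype=bool)])
        member_set.append(np.full(k, set_id))
        member_day.append(np.full(k, d))
        if keep_sets:
            sets.append(
                MatchedSet(
                    set_id,
                    person_id[ci],
                    d,
                    list(person_id[chosen]),
                    tuple(base.loc[ci, list(MATCHING_KEYS)]),
                )
            )
        set_id += 1

    if member_idx:
        all_idx = np.concatenate(member_idx)
        all_day = np.concatenate(member_day)
        data = pd.DataFrame(
            {
                "person_id": person_id[all_idx],
                "set_id": np.concatenate(member_set),
                "is_case": np.concatenate(member_case),
                "event_day": all_day,
                "exposed": ~np.isnan(switch[all_idx])
                & (switch[all_idx] <= all_day),
                "age_at_index": base["age_at_index"].to_numpy()[all_idx],
                "sex": base["sex"].to_numpy()[all_idx],
                "income_quintile": base["income_quintile"].to_numpy()[all_idx],
                "cci_category": base["cci_category"].to_numpy()[all_idx],
                "calendar_period": base["calendar_period"].to_numpy()[all_idx],
            }
        )
    else:
        data = pd.DataFrame(columns=NCC_COLUMNS)
    if n_dropped:
        logger.info("dropped %d case(s) with no suitable control", n_dropped)
    if len(data) and not data["exposed"].any():
        logger.warning("no exposed member in any matched set; the exposure "
                       "effect is not identifiable from this sample")
    return NCCDataset(data=data, n_cases_dropped=n_dropped, m=m, sets=sets)
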