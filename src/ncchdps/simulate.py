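"""Synthetic claims-data generator with known ground truth.

Emulates the structure of linked health-administrative databases for a
chronic-disease cohort treated with disease-modifying drugs (DMDs): a
persons registry, outpatient DMD dispensations, and proxy-code events in
four data dimensions (physician-visit ICD-9 diagnoses, hospital ICD
diagnoses, hospital procedures, and drug identification numbers).

The generative model, per person ``i``:

1. latent confounder ``U_i ~ Normal(0, confounder_sd)``;
2. treatment uptake: ``P(starter) = expit(b0 + confounder_to_exposure·U_i)``;
   starters receive a renewal stream of dispensations of one DMD class,
   with variable days-supplied and a mix of short (bridgeable, <= 30 days)
   and long supply gaps;
3. the true exposure-switch day is the day cumulative supplied days first
   reach the class threshold (180 days for beta-interferon / glatiramer
   acetate, 90 otherwise);
4. death time drawn by inverting the piecewise-constant hazard
   ``h(t) = baseline_hazard · exp(true_log_hr·1{t >= switch} +
   confounder_to_hazard·U_i)``, administratively censored at
   ``admin_end_day``;
5. proxy-code counts in the year before cohort entry are Poisson with
   log-rate ``a_code + code_confounder_loading·U_i``, so the confounder is
   observable only through codes.

All randomness flows from ``config.seed``; per-person streams are derived
sub-streams, so output tables are byte-identical across calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_CCI_WEIGHTS,
    DEFAULT_CLASS_THRESHOLDS,
    DIMENSIONS,
    ConfigError,
    SimulationConfig,
)

PERSON_COLUMNS = [
    "person_id",
    "birth_date",
    "sex",
    "income_quintile",
    "cohort_entry_date",
    "end_date",
    "died",
]
DISPENSATION_COLUMNS = [
    "person_id",
    "drug_class",
    "dispense_date",
    "days_supplied",
    "din_code",
]
CODE_EVENT_COLUMNS = ["person_id", "dimension", "code", "event_date"]
GROUND_TRUTH_COLUMNS = [
    "person_id",
    "latent_confounder",
    "true_switch_day",
    "true_log_hr",
]

#: DMD class -> drug identification number used on dispensation rows.
DMD_DIN_CODES = {
    cls: f"DMD{i:03d}" for i, cls in enumerate(DEFAULT_CLASS_THRESHOLDS)
}

_CLASS_NAMES = list(DEFAULT_CLASS_THRESHOLDS)
_CLASS_PROBS = np.array([0.45, 0.15, 0.15, 0.10, 0.10, 0.05])

# Comorbidity / disease codes seeded into the diagnosis dimensions so the
# comorbidity score varies and the hdPS exclusion list has something to bite.
_PHYSICIAN_SPECIAL = ["250", "340", "410", "428", "493"]
_HOSPITAL_SPECIAL = ["140", "196", "340", "571", "585"]


@dataclass
class RawTables:
    """The three claims-style tables produced by the simulator."""

    persons: pd.DataFrame
    dispensations: pd.DataFrame
    code_events: pd.DataFrame


def _code_universe(dimension: str, n_codes: int) -> list[str]:
    """Deterministic code universe for one dimension."""
    if dimension == "physician_icd":
        special, lo = _PHYSICIAN_SPECIAL, 300
    elif dimension == "hospital_icd":
        special, lo = _HOSPITAL_SPECIAL, 600
    elif dimension == "hospital_proc":
        return [f"{10 + 3 * i:03d}" for i in range(n_codes)]
    elif dimension == "drug_din":
        return [f"{10000019 + 977 * i:08d}" for i in range(n_codes)]
    else:  # pragma: no cover - guarded by DimensionSpec
        raise ConfigError(f"unknown dimension {dimension!r}")
    codes = list(special[: min(len(special), n_codes)])
    c = lo
    while len(codes) < n_codes:
        candidate = f"{c:03d}"
        if candidate not in codes:
            codes.append(candidate)
        c += 7
    return codes[:n_codes]


def _true_switch_day(
    starts: np.ndarray, supplies: np.ndarray, threshold: int
) -> float:
    """Day on which cumulative supplied days first reach ``threshold``.

    The renewal stream never overlaps (each dispensation starts after the
    previous supply ends), so intervals are ``[start, start + supply)`` and
    cumulative counting walks them in order.
    """
    cum = 0
    for start, supply in zip(starts, supplies):
        if cum + supply >= threshold:
            return float(start + (threshold - cum) - 1)
        cum += supply
    return math.nan


def simulate_cohort(config: SimulationConfig) -> tuple[RawTables, pd.DataFrame]:
    """Generate raw tables plus a ground-truth table.

    Returns ``(RawTables, ground_truth)`` where ``ground_truth`` has one row
    per person with the latent confounder value, the true exposure-switch
    day (days since cohort entry; NaN when the threshold is never reached
    within follow-up) and the true conditional log hazard ratio.
    """
    config.validate()
    n = config.n_subjects
    origin = pd.Timestamp(config.calendar_start)
    if n == 0:
        return (
            RawTables(
                persons=pd.DataFrame(columns=PERSON_COLUMNS),
                dispensations=pd.DataFrame(columns=DISPENSATION_COLUMNS),
                code_events=pd.DataFrame(columns=CODE_EVENT_COLUMNS),
            ),
            pd.DataFrame(columns=GROUND_TRUTH_COLUMNS),
        )

    rng = np.random.default_rng(config.seed)
    person_ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- demographics and entry dates -------------------------------------
    u = rng.normal(0.0, config.confounder_sd, size=n)
    sex = np.where(rng.random(n) < 0.72, "female", "male")  # MS-like cohort
    income = rng.integers(1, 6, size=n)
    entry_offset = rng.integers(0, config.entry_spread_days + 1, size=n)
    age_at_entry = rng.uniform(18.0, 60.0, size=n)
    entry = origin + pd.to_timedelta(entry_offset, unit="D")
    birth = entry - pd.to_timedelta(np.round(age_at_entry * 365.25), unit="D")

    # --- treatment uptake --------------------------------------------------
    p_start = 1.0 / (
        1.0 + np.exp(-(config.start_logit_intercept + config.confounder_to_exposure * u))
    )
    is_starter = rng.random(n) < p_start
    start_day = rng.integers(0, config.start_day_max + 1, size=n)
    drug_class_idx = rng.choice(len(_CLASS_NAMES), size=n, p=_CLASS_PROBS)
    therapy_total = rng.exponential(config.therapy_mean_days, size=n)

    disp_person: list[str] = []
    disp_day: list[int] = []
    disp_supply: list[int] = []
    disp_class: list[str] = []
    switch_day = np.full(n, math.nan)

    for i in range(n):
        if not is_starter[i]:
            continue
        sub = np.random.default_rng([config.seed, 7919, i])
        cls = _CLASS_NAMES[drug_class_idx[i]]
        threshold = DEFAULT_CLASS_THRESHOLDS[cls]
        t = int(start_day[i])
        supplied = 0.0
        starts: list[int] = []
        supplies: list[int] = []
        while t < config.admin_end_day and supplied < therapy_total[i]:
            supply = max(
                7,
                int(round(sub.normal(config.dispensation_mean_supply,
                                     config.dispensation_mean_supply / 4.0))),
            )
            starts.append(t)
            supplies.append(supply)
            supplied += supply
            if sub.random() < config.bridged_gap_prob:
                gap = int(sub.integers(0, 27))
            else:
                gap = int(sub.integers(35, 151))
            t = t + supply + gap
        if starts:
            disp_person.extend([person_ids[i]] * len(starts))
            disp_day.extend(starts)
            disp_supply.extend(supplies)
            disp_class.extend([cls] * len(starts))
            switch_day[i] = _true_switch_day(
                np.asarray(starts), np.asarray(supplies), threshold
            )

    # --- death by piecewise-constant hazard inversion ----------------------
    exp_draw = rng.exponential(1.0, size=n)
    lam1 = config.baseline_hazard * np.exp(config.confounder_to_hazard * u)
    lam2 = lam1 * np.exp(config.true_log_hr)
    t_death = exp_draw / lam1
    has_switch = ~np.isnan(switch_day)
    s = np.where(has_switch, switch_day, np.inf)
    late = has_switch & (t_death > s)
    if late.any():
        t_death[late] = s[late] + (exp_draw[late] - lam1[late] * s[late]) / lam2[late]

    died = t_death < config.admin_end_day
    end_day = np.where(died, np.floor(t_death), config.admin_end_day).astype(int)
    end_date = entry + pd.to_timedelta(end_day, unit="D")

    # Switch days beyond follow-up were never observed exposure.
    switch_day = np.where(has_switch & (switch_day <= end_day), switch_day, math.nan)

    persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "birth_date": birth.strftime("%Y-%m-%d"),
            "sex": sex,
            "income_quintile": income,
            "cohort_entry_date": entry.strftime("%Y-%m-%d"),
            "end_date": end_date.strftime("%Y-%m-%d"),
            "died": died,
        }
    )

    if disp_person:
        disp = pd.DataFrame(
            {
                "person_id": disp_person,
                "drug_class": disp_class,
                "dispense_day": disp_day,
                "days_supplied": disp_supply,
            }
        )
        # Dispensations after the end of follow-up never happened.
        end_by_person = pd.Series(end_day, index=person_ids)
        disp = disp[disp["dispense_day"] <= end_by_person.reindex(disp["person_id"]).to_numpy()]
        entry_by_person = pd.Series(entry, index=person_ids)
        disp_dates = entry_by_person.reindex(disp["person_id"]).to_numpy() + pd.to_timedelta(
            disp["dispense_day"].to_numpy(), unit="D"
        )
        dispensations = pd.DataFrame(
            {
                "person_id": disp["person_id"].to_numpy(),
                "drug_class": disp["drug_class"].to_numpy(),
                "dispense_date": pd.DatetimeIndex(disp_dates).strftime("%Y-%m-%d"),
                "days_supplied": disp["days_supplied"].to_numpy(),
                "din_code": disp["drug_class"].map(DMD_DIN_CODES).to_numpy(),
            }
        )
    else:
        dispensations = pd.DataFrame(columns=DISPENSATION_COLUMNS)

    code_events = _simulate_code_events(config, rng, person_ids, u, entry)

    ground_truth = pd.DataFrame(
        {
            "person_id": person_ids,
            "latent_confounder": u,
            "true_switch_day": switch_day,
            "true_log_hr": config.true_log_hr,
        }
    )
    tables = RawTables(
        persons=persons.reset_index(drop=True),
        dispensations=dispensations.sort_values(
            ["person_id", "dispense_date"], kind="stable"
        ).reset_index(drop=True),
        code_events=code_events,
    )
    return tables, ground_truth


def _simulate_code_events(
    config: SimulationConfig,
    rng: np.random.Generator,
    person_ids: np.ndarray,
    u: np.ndarray,
    entry: pd.DatetimeIndex,
) -> pd.DataFrame:
    """Poisson proxy-code events, mostly within the pre-entry year."""
    n = len(person_ids)
    frames = []
    for dim in DIMENSIONS:
        codes = _code_universe(dim, config.n_codes_per_dimension)
        base = rng.normal(config.code_base_log_rate, config.code_rate_sd, len(codes))
        lam = np.exp(base[None, :] + config.code_confounder_loading * u[:, None])
        lam = np.minimum(lam, 20.0)
        counts = rng.poisson(lam)  # persons x codes
        pi, ci = np.nonzero(counts)
        reps = counts[pi, ci]
        pidx = np.repeat(pi, reps)
        cidx = np.repeat(ci, reps)
        n_ev = len(pidx)
        if n_ev == 0:
            continue
        # 80% of events fall in the 1-year pre-entry assessment window, the
        # rest after entry, so window filtering is actually exercised.
        pre = rng.random(n_ev) < 0.8
        offset = np.where(
            pre, -rng.integers(1, 366, size=n_ev), rng.integers(0, 366, size=n_ev)
        )
        dates = entry[pidx] + pd.to_timedelta(offset, unit="D")
        code_arr = np.array(codes, dtype=object)[cidx]
        if dim in ("physician_icd", "hospital_icd"):
            sub = rng.integers(0, 10, size=n_ev).astype(str)
            code_arr = np.char.add(np.char.add(code_arr.astype(str), "."), sub)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": person_ids[pidx],
                    "dimension": dim,
                    "code": code_arr,
                    "event_date": pd.DatetimeIndex(dates).strftime("%Y-%m-%d"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CODE_EVENT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["person_id", "dimension", "code", "event_date"], kind="stable"
    ).reset_index(drop=True)
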