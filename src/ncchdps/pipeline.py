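"""End-to-end pipeline: simulate/load -> cohort -> NCC -> hdPS -> IPTW ->
outcome models (-> outputation), from a single :class:`RunConfig`.

Every stage's tabular output can be persisted to an output directory; each
persisted file carries the resolved configuration hash so artifacts from
different runs cannot be mixed silently.  A second run with the same
configuration reproduces the report exactly.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cohort import assemble_cohort
from .config import (
    CciWeightMap,
    DimensionSpec,
    ExposureRule,
    PSModelSpec,
    RunConfig,
    default_hdps_exclusions,
    dump_run_config,
)
from .hdps import (
    RecurrenceMatrix,
    build_recurrence,
    count_codes,
    prevalence_filter,
    priorities_frame,
    prioritize_bross,
    prioritize_cox_lasso,
    prioritize_rsf,
)
from .io import read_tables
from .models import (
    fit_conditional_logistic,
    fit_naive_cox,
    fit_time_varying_cox,
    split_counting_process,
)
from .ncc import NCCDataset, assemble_ncc
from .outputation import repeat_ncc
from .simulate import simulate_cohort
from .weights import balance_gate, balance_table, estimate_ps, stabilized_weights

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Everything a run computed, regenerable from its persisted files."""

    config: RunConfig
    config_hash: str
    estimates: pd.DataFrame
    weight_summary: dict[str, dict[str, float]]
    balance: pd.DataFrame
    counts: dict[str, int]
    priorities: pd.DataFrame
    outputation: pd.DataFrame | None = None
    artifacts: dict[str, Any] = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "estimates": self.estimates.to_dict(orient="records"),
            "weight_summary": self.weight_summary,
            "balance": self.balance.to_dict(orient="records"),
            "counts": self.counts,
        }
        return json.dumps(payload, indent=2, default=float)


def _hdps_stage(
    config: RunConfig,
    raw_code_events: pd.DataFrame,
    cohort: pd.DataFrame,
    ncc: NCCDataset,
):
    """hdPS steps i-v: counts, prevalence filter, recurrence, priorities."""
    exclusions = default_hdps_exclusions()
    counts = []
    for dim in config.dimensions:
        spec = DimensionSpec(
            name=dim,
            code_granularity=config.granularity,
            top_n_prevalence=config.top_n_prevalence,
            excluded_codes=exclusions,
        )
        counts.append(count_codes(raw_code_events, cohort, spec))
    counts = pd.concat(counts, axis=1)
    retained = prevalence_filter(counts, config.top_n_prevalence)
    recurrence = build_recurrence(counts[retained])

    if config.prioritize_on == "cohort":
        surv_index = cohort["person_id"]
        time = cohort["followup_days"].to_numpy(dtype=float) + 1.0
        event = cohort["event"].to_numpy(dtype=bool)
        X = recurrence.data.reindex(surv_index)
    else:  # NCC sample (deduplicated persons)
        members = ncc.data.drop_duplicates("person_id")["person_id"]
        sub = cohort.set_index("person_id").loc[members]
        time = sub["followup_days"].to_numpy(dtype=float) + 1.0
        event = sub["event"].to_numpy(dtype=bool)
        X = recurrence.data.reindex(members)

    if config.prioritizer == "cox-lasso":
        scores = prioritize_cox_lasso(
            X, time, event, k=config.top_k, seed=config.seed
        )
    elif config.prioritizer == "rsf":
        scores = prioritize_rsf(X, time, event, k=config.top_k, seed=config.seed)
    else:
        scores = prioritize_bross(
            recurrence.data.reindex(ncc.data["person_id"]),
            ncc.data["exposed"].to_numpy(),
            ncc.data["is_case"].to_numpy(),
            k=config.top_k,
        )
    return recurrence, scores


def _weighting_stage(
    config: RunConfig, ncc: NCCDataset, recurrence: RecurrenceMatrix, top: list
):
    """hdPS steps vi-vii support: PS, stabilized truncated weights, balance."""
    hd_names = [s.covariate for s in top]
    joined = ncc.data.join(
        recurrence.data[hd_names], on="person_id"
    )
    ps_spec = PSModelSpec(method=config.ps_method, seed=config.seed)
    scores = estimate_ps(joined, ps_spec, hd_covariates=hd_names)
    wv = stabilized_weights(
        scores, joined["exposed"].to_numpy(), config.truncate_quantile
    )
    balance = balance_table(
        joined,
        list(ps_spec.investigator_covariates),
        weights=wv.truncated,
        threshold=config.smd_threshold,
    )
    readjust = balance_gate(balance, config.smd_threshold)
    return joined, wv, balance, readjust


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute all stages in order and assemble the run report."""
    if config.input_dir is not None:
        tables = read_tables(config.input_dir)
        logger.info("stage simulate: skipped, read tables from %s", config.input_dir)
    else:
        tables, _ = simulate_cohort(config.simulation)
        logger.info("stage simulate: %d persons", len(tables.persons))

    build = assemble_cohort(
        tables,
        rule=ExposureRule(mode=config.exposure_mode),
        weights=CciWeightMap(),
        study_end=config.study_end,
    )
    cohort = build.cohort
    logger.info(
        "stage cohort: %d rows, %d excluded", len(cohort), len(build.exclusions)
    )

    ncc = assemble_ncc(cohort, m=config.controls_per_case, seed=config.seed)
    logger.info(
        "stage ncc: %d sets (%d controls), %d case(s) dropped",
        ncc.n_cases, ncc.n_controls, ncc.n_cases_dropped,
    )

    recurrence, top = _hdps_stage(config, tables.code_events, cohort, ncc)
    logger.info(
        "stage hdps: %d recurrence covariates (%d duplicate columns), top %d kept",
        recurrence.data.shape[1], len(recurrence.dropped_duplicates), len(top),
    )

    joined, wv, balance, readjust = _weighting_stage(config, ncc, recurrence, top)
    logger.info("stage weights: %s re-adjusted in outcome model", readjust or "none")

    estimates = []
    est_plain = fit_conditional_logistic(ncc.data, adjust=("age_at_index", "sex"))
    estimates.append(est_plain.summary_row())
    iptw_adjust = tuple(readjust)
    est_iptw = fit_conditional_logistic(
        joined, adjust=iptw_adjust, weights=wv.truncated
    )
    estimates.append(est_iptw.summary_row())

    rows = split_counting_process(cohort)
    est_cox = fit_time_varying_cox(rows)
    estimates.append(est_cox.summary_row())
    est_naive = fit_naive_cox(cohort)
    estimates.append(est_naive.summary_row())

    outputation_frame = None
    if config.reps > 1:
        pooled = repeat_ncc(
            cohort,
            m=config.controls_per_case,
            n_reps=config.reps,
            base_seed=config.seed,
        )
        outputation_frame = pooled.frame()
        lo, hi = pooled.ci95
        estimates.append(
            {
                "estimator": f"ncc-clogit-outputation-{config.reps}",
                "log_hr": pooled.pooled_log_hr,
                "se": pooled.pooled_se,
                "hr": pooled.pooled_hr,
                "ci_low": lo,
                "ci_high": hi,
                "n": pooled.n_reps,
            }
        )

    report = RunReport(
        config=config,
        config_hash=config.config_hash(),
        estimates=pd.DataFrame(estimates),
        weight_summary={
            "stabilized": wv.summary("stabilized"),
            "truncated": wv.summary("truncated"),
        },
        balance=balance,
        counts={
            "persons": len(tables.persons),
            "cohort": len(cohort),
            "excluded": len(build.exclusions),
            "cases": ncc.n_cases,
            "controls": ncc.n_controls,
            "cases_dropped": ncc.n_cases_dropped,
            "uninformative_sets": int(
                est_plain.diagnostics.get("n_uninformative_sets", 0)
            ),
            "recurrence_covariates": recurrence.data.shape[1],
            "selected_covariates": len(top),
        },
        priorities=priorities_frame(top),
        outputation=outputation_frame,
        artifacts={
            "cohort": cohort,
            "ncc": ncc,
            "recurrence": recurrence,
            "weights": wv,
            "estimates_obj": {
                "ncc-clogit": est_plain,
                "ncc-clogit-iptw": est_iptw,
                "cox-tv": est_cox,
                "cox-naive-ever-exposed": est_naive,
            },
        },
    )
    if out_dir is not None:
        _persist(report, joined, Path(out_dir))
    return report


def _persist(report: RunReport, joined: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    h = report.config_hash
    frames = {
        "cohort.csv": report.artifacts["cohort"],
        "ncc.csv": report.artifacts["ncc"].data,
        "priorities.csv": report.priorities,
        "balance.csv": report.balance,
        "estimates.csv": report.estimates,
        "weights.csv": pd.DataFrame(
            {
                "row": np.arange(len(joined)),
                "person_id": joined["person_id"],
                "score": report.artifacts["weights"].scores,
                "stabilized_weight": report.artifacts["weights"].stabilized,
                "truncated_weight": report.artifacts["weights"].truncated,
            }
        ),
    }
    if report.outputation is not None:
        frames["outputation.csv"] = report.outputation
    for name, df in frames.items():
        df = df.copy()
        df["config_hash"] = h
        df.to_csv(out_dir / name, index=False)
    dump_run_config(report.config, out_dir / "resolved_config.yaml")
    (out_dir / "report.json").write_text(report.to_json())


SWEEP_AXES = (
    "controls_per_case",
    "prioritizer",
    "top_k",
    "top_n_prevalence",
    "dimensions",
    "granularity",
    "ps_method",
    "smd_threshold",
    "reps",
)


def sensitivity_sweep(
    base: RunConfig, axes: dict[str, list[Any]]
) -> pd.DataFrame:
    """Run the pipeline over the Cartesian product of requested settings.

    Returns one row per scenario x estimator (the shape of a sensitivity
    table); per-scenario failures are recorded and the sweep continues.
    """
    unknown = set(axes) - set(SWEEP_AXES)
    if unknown:
        raise ValueError(f"unknown sweep axes: {sorted(unknown)}")
    keys = sorted(axes)
    rows = []
    combos = itertools.product(*(axes[k] for k in keys)) if keys else [()]
    for combo in combos:
        overrides = dict(zip(keys, combo))
        scenario = ", ".join(f"{k}={v}" for k, v in overrides.items()) or "base"
        cfg = replace(base, **overrides)
        try:
            report = run_pipeline(cfg)
            for rec in report.estimates.to_dict(orient="records"):
                rows.append({"scenario": scenario, **rec})
        except Exception as err:  # noqa: BLE001 - sweep-level recovery
            logger.warning("scenario %s failed: %s", scenario, err)
            rows.append({"scenario": scenario, "estimator": "error", "note": str(err)})
    return pd.DataFrame(rows)
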