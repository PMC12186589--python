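"""Configuration objects shared across the pipeline.

Every stage of the pipeline is driven by one of the small dataclasses
defined here; :class:`RunConfig` composes them for end-to-end runs.  All
of them round-trip through plain dicts (and hence YAML/JSON) so that a
run's resolved configuration can be persisted next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

DIMENSIONS = ("physician_icd", "hospital_icd", "hospital_proc", "drug_din")

#: Drug classes requiring 180 days of cumulative supply before a person
#: counts as exposed; every other class switches at 90 days.
LONG_THRESHOLD_CLASSES = ("beta_interferon", "glatiramer_acetate")

DEFAULT_CLASS_THRESHOLDS = {
    "beta_interferon": 180,
    "glatiramer_acetate": 180,
    "natalizumab": 90,
    "fingolimod": 90,
    "dimethyl_fumarate": 90,
    "teriflunomide": 90,
}


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic claims-data generator.

    The generator emulates linked health-administrative tables: a persons
    registry, outpatient drug dispensations for disease-modifying drugs
    (DMDs), and proxy-code events in four data dimensions.  A latent
    per-person confounder ``U ~ Normal(0, confounder_sd)`` drives treatment
    uptake (``confounder_to_exposure``, log-odds scale), the death hazard
    (``confounder_to_hazard``, log-hazard scale) and the Poisson rates of
    proxy codes (``code_confounder_loading``), so residual confounding can
    be transmitted through codes alone.
    """

    n_subjects: int = 2000
    seed: int = 12345
    #: Conditional log hazard ratio of exposure on death (the estimand).
    true_log_hr: float = math.log(0.7)
    confounder_sd: float = 1.0
    confounder_to_exposure: float = 0.6
    confounder_to_hazard: float = 0.5
    n_codes_per_dimension: int = 50
    code_confounder_loading: float = 0.7
    #: Daily baseline death hazard.
    baseline_hazard: float = 2e-4
    #: Administrative censoring, days after cohort entry.
    admin_end_day: int = 3650
    dispensation_mean_supply: int = 60
    calendar_start: str = "1996-01-01"
    # Secondary knobs of the generative model (documented in docs/methods.md).
    entry_spread_days: int = 6200
    start_logit_intercept: float = 0.0
    start_day_max: int = 900
    therapy_mean_days: float = 900.0
    bridged_gap_prob: float = 0.75
    code_base_log_rate: float = math.log(0.08)
    code_rate_sd: float = 0.5

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError(f"n_subjects must be >= 0, got {self.n_subjects}")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.confounder_sd < 0:
            raise ConfigError("confounder_sd must be >= 0")
        if self.n_codes_per_dimension < 1:
            raise ConfigError("n_codes_per_dimension must be >= 1")
        if self.dispensation_mean_supply <= 0:
            raise ConfigError("dispensation_mean_supply must be > 0")


@dataclass(frozen=True)
class ExposureRule:
    """Cumulative-use exposure definition.

    ``class_thresholds`` maps drug class to the cumulative number of supplied
    days after which a person counts as exposed (180 for beta-interferon and
    glatiramer acetate, 90 for the newer DMD classes).  Supply runs of the
    same class separated by gaps of at most ``max_gap`` days are contiguous;
    in the default ``"cumulative"`` mode supplied days accumulate across the
    whole history, while ``"episode"`` mode restarts the counter whenever a
    gap exceeds ``max_gap``.
    """

    class_thresholds: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_THRESHOLDS)
    )
    default_threshold: int = 90
    max_gap: int = 30
    mode: str = "cumulative"  # or "episode"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.class_thresholds.values()):
            raise ConfigError("exposure thresholds must be > 0")
        if self.default_threshold <= 0:
            raise ConfigError("default_threshold must be > 0")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        if self.mode not in ("cumulative", "episode"):
            raise ConfigError(f"unknown exposure mode {self.mode!r}")

    def threshold_for(self, drug_class: str) -> int:
        return int(self.class_thresholds.get(drug_class, self.default_threshold))


#: Weighted comorbidity map standing in for the Charlson index on synthetic
#: codes: 3-digit ICD-9-style code -> (condition group, weight).  Hemiplegia/
#: paraplegia codes are excluded so neurological deficits of the study disease
#: are not misread as comorbidity.
DEFAULT_CCI_WEIGHTS = {
    "410": ("myocardial_infarction", 1),
    "428": ("heart_failure", 1),
    "443": ("peripheral_vascular", 1),
    "493": ("copd", 1),
    "571": ("liver_disease", 1),
    "250": ("diabetes", 1),
    "585": ("renal_disease", 2),
    "140": ("malignancy", 2),
    "196": ("metastatic", 6),
}

DEFAULT_CCI_EXCLUDED = frozenset({"342", "344"})  # hemiplegia / paraplegia


@dataclass(frozen=True)
class CciWeightMap:
    """Configurable code -> weight map for the comorbidity score.

    ``weights`` maps a 3-digit diagnosis code to ``(condition_group,
    weight)``; distinct condition groups are counted once regardless of how
    often or through how many codes they appear.  ``excluded_codes`` are
    ignored entirely.
    """

    weights: Mapping[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_CCI_WEIGHTS)
    )
    excluded_codes: frozenset[str] = DEFAULT_CCI_EXCLUDED

    def __post_init__(self) -> None:
        if any(w < 1 for _, w in self.weights.values()):
            raise ConfigError("CCI weights must be >= 1")


@dataclass(frozen=True)
class DimensionSpec:
    """Configuration of one proxy-code data dimension for the hdPS engine."""

    name: str
    code_granularity: int = 3  # 3- or 4-digit ICD truncation
    top_n_prevalence: int = 1000
    excluded_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.name not in DIMENSIONS:
            raise ConfigError(
                f"unknown dimension {self.name!r}; expected one of {DIMENSIONS}"
            )
        if self.code_granularity not in (3, 4):
            raise ConfigError("code_granularity must be 3 or 4")
        if self.top_n_prevalence < 1:
            raise ConfigError("top_n_prevalence must be >= 1")


@dataclass(frozen=True)
class PSModelSpec:
    """Propensity-score model specification (hdPS steps vi-vii support)."""

    method: str = "lasso-logistic"  # or "gradient-boosted-trees"
    investigator_covariates: tuple[str, ...] = ("age_at_index", "sex")
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0
    clip_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in ("lasso-logistic", "gradient-boosted-trees"):
            raise ConfigError(f"unknown PS method {self.method!r}")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # read raw tables instead of simulating
    controls_per_case: int = 4
    prioritizer: str = "cox-lasso"  # cox-lasso | rsf | bross
    top_k: int = 200
    top_n_prevalence: int = 1000
    dimensions: tuple[str, ...] = DIMENSIONS
    granularity: int = 3
    ps_method: str = "lasso-logistic"
    smd_threshold: float = 0.2
    truncate_quantile: float = 0.99
    reps: int = 1
    seed: int = 2026
    exposure_mode: str = "cumulative"
    study_end: str = "2017-12-31"
    #: Survival data for covariate prioritization: the full analytic cohort
    #: (default) or the NCC sample only.
    prioritize_on: str = "cohort"

    def __post_init__(self) -> None:
        if self.controls_per_case < 1:
            raise ConfigError("controls_per_case must be >= 1")
        if self.prioritizer not in ("cox-lasso", "rsf", "bross"):
            raise ConfigError(f"unknown prioritizer {self.prioritizer!r}")
        if not 0 < self.truncate_quantile <= 1:
            raise ConfigError("truncate_quantile must be in (0, 1]")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")
        unknown = set(self.dimensions) - set(DIMENSIONS)
        if unknown:
            raise ConfigError(f"unknown dimensions: {sorted(unknown)}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    sim = SimulationConfig(**raw.pop("simulation", {}))
    for key in ("dimensions", "investigator_covariates"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(simulation=sim, **raw)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def default_hdps_exclusions(cci: CciWeightMap | None = None) -> frozenset[str]:
    """Codes excluded from proxy dimensions: comorbidity-index codes, the
    MS diagnosis codes, and DMD drug identification numbers."""
    cci = cci or CciWeightMap()
    codes = set(cci.weights) | set(cci.excluded_codes) | {"340", "G35"}
    codes |= {f"DMD{i:03d}" for i in range(len(DEFAULT_CLASS_THRESHOLDS))}
    return frozenset(codes)
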