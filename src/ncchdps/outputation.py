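"""Multiple outputation: repeat the random control sampling and pool.

Control selection makes the NCC estimate noisy; repeating the sampling R
times and averaging stabilizes it.  The pooled variance follows the
modified multiple-outputation rule

    V = within - (1 - 1/R) * between,

with ``within`` the mean squared standard error across repetitions and
``between`` the sample variance of the repetition estimates.  When the
subtraction turns non-positive (possible at small R), the rule falls back
to ``within`` with a logged warning.  Setting ``finite_r=False`` subtracts
the full between-variance instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import EffectEstimate, Z95, fit_conditional_logistic
from .ncc import NCCDataset, assemble_ncc

logger = logging.getLogger(__name__)


@dataclass
class OutputationResult:
    estimates: list[tuple[float, float]]  # (log_hr, se) per repetition
    pooled_log_hr: float
    within_var: float
    between_var: float
    pooled_se: float
    n_reps: int
    n_failed: int = 0
    fallback_used: bool = False

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.pooled_log_hr - Z95 * self.pooled_se)),
            float(np.exp(self.pooled_log_hr + Z95 * self.pooled_se)),
        )

    def frame(self) -> pd.DataFrame:
        rows = [
            {"repetition": i, "log_hr": b, "se": s}
            for i, (b, s) in enumerate(self.estimates)
        ]
        rows.append(
            {"repetition": "pooled", "log_hr": self.pooled_log_hr,
             "se": self.pooled_se}
        )
        return pd.DataFrame(rows)


def pool_estimates(
    estimates: Sequence[tuple[float, float]],
    finite_r: bool = True,
) -> OutputationResult:
    """Pool per-repetition (log_hr, se) pairs with the modified rule."""
    if not estimates:
        raise ValueError("no estimates to pool")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    r = len(betas)
    pooled = float(betas.mean())
    within = float(np.mean(ses**2))
    between = float(betas.var(ddof=1)) if r > 1 else 0.0
    coef = (1.0 - 1.0 / r) if finite_r else 1.0
    variance = within - coef * between
    fallback = False
    if variance <= 0:
        logger.warning(
            "outputation variance %-.4g <= 0; falling back to within-variance",
            variance,
        )
        variance, fallback = within, True
    return OutputationResult(
        estimates=[(float(b), float(s)) for b, s in estimates],
        pooled_log_hr=pooled,
        within_var=within,
        between_var=between,
        pooled_se=float(np.sqrt(variance)),
        n_reps=r,
        fallback_used=fallback,
    )


def repeat_ncc(
    cohort: pd.DataFrame,
    m: int = 4,
    n_reps: int = 100,
    base_seed: int = 0,
    adjust: Sequence[str] = ("age_at_index", "sex"),
    weight_fn: Callable[[NCCDataset], np.ndarray] | None = None,
    finite_r: bool = True,
) -> OutputationResult:
    """Repeat control sampling + conditional-logistic estimation.

    Repetition ``r`` samples controls with seed ``base_seed + r``; the
    cohort (and any upstream hdPS prioritization feeding ``weight_fn``) is
    fixed across repetitions.  ``weight_fn`` maps the repetition's NCC
    dataset to per-row IPT weights, enabling outputation of the hdPS
    pipeline.  Repetitions failing estimation are skipped and counted;
    more than 20% failures is an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    estimates: list[tuple[float, float]] = []
    n_failed = 0
    for r in range(n_reps):
        try:
            ncc = assemble_ncc(cohort, m=m, seed=base_seed + r)
            w = weight_fn(ncc) if weight_fn is not None else None
            est: EffectEstimate = fit_conditional_logistic(
                ncc.data, adjust=adjust, weights=w
            )
            estimates.append((est.log_hr, est.se))
        except Exception as err:  # noqa: BLE001 - repetition-level recovery
            n_failed += 1
            logger.warning("repetition %d failed: %s", r, err)
    if n_failed > 0.2 * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} outputation repetitions failed estimation"
        )
    result = pool_estimates(estimates, finite_r=finite_r)
    result.n_failed = n_failed
    return result
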