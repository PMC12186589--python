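"""High-dimensional propensity score weighting inside the NCC design.

Here the confounder is latent and leaks only into proxy-code rates: the
unadjusted NCC estimate is biased toward the null, and reweighting by a
propensity score built from the top recurrence covariates moves the
estimate back toward the truth.  Runs the packaged end-to-end pipeline.
"""

import numpy as np

from ncchdps import RunConfig, SimulationConfig, run_pipeline

config = RunConfig(
    simulation=SimulationConfig(n_subjects=2000, seed=3),
    seed=42,
    prioritizer="cox-lasso",
    top_k=200,
)
report = run_pipeline(config)

print(f"true HR: {np.exp(config.simulation.true_log_hr):.3f}")
print(report.estimates[["estimator", "hr", "ci_low", "ci_high"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\ntruncated weight summary:",
      {k: round(v, 3) for k, v in report.weight_summary["truncated"].items()})
print("\nbalance after weighting:")
print(report.balance.to_string(index=False))
print(f"\nselected {report.counts['selected_covariates']} of "
      f"{report.counts['recurrence_covariates']} recurrence covariates")
# ncc-clogit is confounded toward the null; ncc-clogit-iptw applies the
# stabilized truncated hdPS weights and lands closer to the true 0.70.
# cox-naive-ever-exposed shows what immortal time alone would do.
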