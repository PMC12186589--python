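"""Immortal time bias: naive ever-exposed Cox vs nested case-control.

Simulates a no-confounding cohort with a true conditional hazard ratio of
0.7, then compares three estimators.  The naive time-fixed analysis
misclassifies pre-switch person-time as exposed and overstates benefit;
the NCC conditional-logistic estimate and the full-cohort time-varying Cox
both recover the truth.
"""

import numpy as np

from ncchdps import (
    SimulationConfig,
    assemble_cohort,
    assemble_ncc,
    fit_conditional_logistic,
    fit_naive_cox,
    fit_time_varying_cox,
    simulate_cohort,
    split_counting_process,
)

config = SimulationConfig(
    n_subjects=3000,
    seed=7,
    confounder_to_exposure=0.0,
    confounder_to_hazard=0.0,
    code_confounder_loading=0.0,
)
tables, truth = simulate_cohort(config)
cohort = assemble_cohort(tables).cohort

ncc = assemble_ncc(cohort, m=4, seed=11)
est_ncc = fit_conditional_logistic(ncc.data)
est_cox = fit_time_varying_cox(split_counting_process(cohort))
est_naive = fit_naive_cox(cohort)

print(f"true HR: {np.exp(truth['true_log_hr'].iloc[0]):.3f}")
for est in (est_ncc, est_cox, est_naive):
    lo, hi = est.ci95
    print(f"{est.estimator:24s} HR {est.hr:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(f"matched sets: {ncc.n_cases} cases, {ncc.n_controls} controls, "
      f"{ncc.n_cases_dropped} case(s) without a suitable control")
# Expect the first two HRs near 0.70 and the naive HR well below it: the
# immortal pre-switch span inflates the apparent protective effect.
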