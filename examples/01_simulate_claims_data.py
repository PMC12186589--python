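"""Generate synthetic claims-style tables with known ground truth.

Builds a 2000-person cohort with a latent confounder driving treatment
uptake, death, and proxy-code rates, writes the three raw CSV tables, and
prints what the generator produced.
"""

from ncchdps import SimulationConfig, simulate_cohort, write_tables

config = SimulationConfig(n_subjects=2000, seed=12345)
tables, truth = simulate_cohort(config)
write_tables(tables, "scratch/example_raw", ground_truth=truth)

n_exposed = truth["true_switch_day"].notna().sum()
print(f"persons:        {len(tables.persons)}")
print(f"dispensations:  {len(tables.dispensations)}")
print(f"code events:    {len(tables.code_events)}")
print(f"deaths:         {tables.persons['died'].sum()}")
print(f"reached the cumulative-use threshold: {n_exposed}")
print(f"true conditional log HR: {truth['true_log_hr'].iloc[0]:.4f}")
# The switch day is when cumulative supplied days first reach the class
# threshold (180 days for beta-interferon/glatiramer, 90 otherwise); people
# dying or censored before that day count as unexposed for their whole
# follow-up.
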