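# Methods

`ncchdps` implements a survival-analysis pipeline that addresses two biases
jointly in claims-style observational data on a time-varying drug exposure:

* **Immortal time bias.** Defining exposure as "ever reached the
  cumulative-use threshold" misclassifies the pre-threshold span — during
  which an eventually-exposed person could not die as an exposed case — as
  exposed person-time, inflating apparent benefit. The pipeline removes it
  by nested case–control (NCC) sampling with incidence density risk sets:
  each death is matched, at its event time, to controls still at risk, and
  every member's exposure is evaluated *at that event time*. The
  time-dependent exposure becomes a time-fixed covariate inside matched
  sets, and the conditional-logistic odds ratio estimates the hazard ratio.
* **Residual confounding.** A high-dimensional propensity score (hdPS) is
  built from proxy codes in four claims dimensions and applied as
  stabilized, truncated inverse-probability-of-treatment weights (IPTW)
  inside the conditional-logistic outcome model.

## Data model and simulator

The three raw tables mirror linked health-administrative databases: a
persons registry, outpatient drug dispensations (drug class, dispense date,
days supplied, drug identification number), and dated code events in four
proxy dimensions (physician-visit ICD-9 diagnoses, hospital ICD-9/10
diagnoses, hospital procedures, drug identification numbers).

Because real linked registries of this kind are not redistributable, the
package ships a generator with known ground truth. Per person *i*:

1. latent confounder `U_i ~ Normal(0, confounder_sd)` (default sd 1);
2. treatment uptake `P(starter) = expit(confounder_to_exposure * U_i)`
   (default loading 0.6, ~50% starters); starters receive a renewal stream
   of dispensations of one disease-modifying-drug (DMD) class with
   days-supplied ~ Normal(60, 15) clipped at 7 and gaps that are short
   (≤ 26 days, bridgeable) with probability 0.75 and long (35–150 days)
   otherwise, so the ≤ 30-day gap rule is genuinely exercised;
3. the true switch day is the day cumulative supplied days reach the class
   threshold — 180 for beta-interferon / glatiramer acetate, 90 for the
   newer classes;
4. death time by closed-form inversion of the piecewise-constant hazard
   `h(t) = baseline_hazard * exp(true_log_hr * 1{t >= switch} +
   confounder_to_hazard * U_i)` (defaults: 2e-4/day, log 0.7, loading 0.5),
   administratively censored at `admin_end_day` (default 3650);
5. proxy-code counts in the pre-entry year are Poisson with log-rate
   `a_code + code_confounder_loading * U_i` (per-code base rates
   ~ Normal(log 0.08, 0.5), loading 0.7, 50 codes per dimension by
   default), so the confounder is observable *only through codes* — the
   setting the hdPS step is meant for. 20% of code events fall after entry
   to exercise window filtering.

Entry dates spread over ~17 calendar years so the four calendar-period
strata are populated; age at entry is Uniform(18, 60); the sex mix (72%
female) matches a multiple-sclerosis-like cohort. All randomness flows
from one seed; per-person dispensation streams use derived sub-streams, so
tables are byte-identical across calls.

What the generator does **not** emulate: real ICD code semantics and
correlation structure, seasonality, multiple causes of death, emigration
beyond a single censoring date, exposure misclassification, or
informative censoring. Passing tests therefore demonstrate correctness of
the estimators under a known, well-behaved generative model — not
robustness to every pathology of real claims data.

## Cohort construction

Day 0 is the index date; intervals are half-open `[start, end)`. The
simulator's entry date is the index; for raw registry-style data
`derive_index_date` implements the latest-of rule (first disease evidence,
first DMD dispensation, 18th birthday, study start). Follow-up runs to the
earliest of death, administrative censoring, and the study end
(1996-01-01 … 2017-12-31 by default).

**Exposure accrual.** Same-class supplies are queued end-to-end (a
dispensation arriving while supply is running starts when it is
exhausted), so overlapping supply is never double-counted. Covered days
before the index do not count. In the default *cumulative* mode supplied
days accumulate over the whole history and the ≤ 30-day gap rule is
informational; in the optional *episode* mode a gap > 30 days between
coverage runs resets the counter, which is the strict reading of
"contiguous exposure". The switch day is the calendar day the cumulative
count first reaches the class threshold, minimized over classes. A
brute-force day-grid counter (mark each covered day, walk forward) serves
as the test oracle for both modes.

**Comorbidity.** A configurable code→(condition group, weight) map stands
in for the Charlson index (real coding tables are out of scope on
synthetic codes): distinct condition groups present in the 1-year
pre-index window contribute their weight once, hemiplegia/paraplegia codes
are excluded so disease-related deficits are not misread as comorbidity,
and the score is bucketed as {0, 1, 2, 3+}.

## Nested case–control sampling

For each death at day *d*, the risk set is everyone with follow-up ≥ *d*
(cases belong to their own risk set); the control pool additionally
excludes persons dying at *d* and is restricted to exact equality on the
matching key (income quintile, comorbidity category — the 4-level bucket,
matching the usual presentation — and calendar period). Up to *m* controls
(default 4; 8 as a sensitivity) are drawn uniformly without replacement
within a set and with replacement across sets, so a person can serve as a
control repeatedly and later become a case. Cases with an empty pool are
dropped and counted. Exposure is time-matched: `switch_day <= d`.

## Outcome models

**Conditional logistic regression** (the primary estimator) maximizes

    l(beta) = sum_s w_case [ eta_case − log sum_{j in s} w_j exp(eta_j) ]

by Newton–Raphson with step halving (analytic gradient and Hessian,
convergence at max |score| < 1e-7 and relative log-likelihood change
≤ 1e-8, start at zero). At unit weights this is the exact conditional
likelihood given one case per set; with weights it is the weighted
pseudo-likelihood convention of `survival::clogit` (per-row weights inside
the risk-set sum, the case weight multiplying the set term). Standard
errors come from White's sandwich estimator clustered on matched set.
Covariates with no within-set variation are dropped with a log entry;
|coefficient| > 15 flags possible separation; degenerate inputs (no
informative sets, single exposure level) raise estimation errors rather
than returning numbers.

**Counting-process Cox comparator.** Person-time is split at the switch
day; a death during day *d* is placed at time *d* + 1, which makes the Cox
risk set at each event time coincide exactly with the NCC risk set
{follow-up ≥ d} and keeps day-0 deaths representable. The model is fitted
with lifelines' `CoxTimeVaryingFitter` (Efron ties), stratified by the
matching covariates, adjusting for age and sex. A deliberately naive
time-fixed "ever exposed" Cox fit is provided as the immortal-time foil.

**Diagnostics.** Kaplan–Meier curves and the two-group log-rank test wrap
lifelines. For null-calibration work the package provides the Mantel–Byar
test — the log-rank with time-matched group membership, equal to the
time-varying Cox score test at beta 0 — because the ever-exposed log-rank
is intrinsically anticonservative under the null (that anticonservatism is
itself asserted in a test). Proportional-hazards checks use lifelines'
scaled-Schoenfeld test (rank transform) for plain Cox fits and a
covariate × log(time) interaction Wald test for counting-process fits,
where Schoenfeld machinery is unavailable.

## hdPS engine

Steps (i)–(v) of the seven-step algorithm:

1. per-dimension code counts in the 1-year pre-index window, ICD codes
   truncated to 3 digits (4-digit "XXX.X" as a sensitivity); codes that
   define the comorbidity index, the disease itself, or the DMD drug
   identification numbers are excluded to avoid double counting;
2. prevalence filter: the `top_n` (default 1000) codes per dimension by
   carrier count descending — the "most prevalent" reading; the classic
   hdPS prevalence-closest-to-0.5 ordering is deliberately not the
   default. Ties break lexicographically so results are deterministic;
3. recurrence expansion: per code, binary covariates for count ≥ 1,
   ≥ carrier median, ≥ carrier 75th percentile. Quantiles are computed
   among carriers only with NumPy's linear interpolation and applied as
   `count >= threshold`; duplicate columns are dropped with their
   thresholds still recorded;
4. prioritization for the time-to-death outcome, by default on the full
   analytic cohort (the NCC-sample alternative is a config option):
   * **Cox-LASSO**: L1-penalized Cox over a 40-point lambda path on
     internally standardized columns; lambda chosen by 5-fold
     event-stratified cross-validation maximizing held-out Breslow partial
     log-likelihood (the minimum-prediction-error rule); ranking by
     |coefficient| mapped back to the original 0/1 coding, zeros last,
     ties lexicographic;
   * **survival forest**: scikit-survival's log-rank forest with seeded
     permutation importance (concordance loss on a ≤ 600-row subsample —
     the forest's impurity values are not defined for its log-rank
     splitter, so permutation importance is the package's importance
     measure);
   * **Bross multiplier**: `[pc1 (RR−1) + 1] / [pc0 (RR−1) + 1]` ranked by
     |log multiplier|, with plug-in prevalences from the NCC sample, the
     outcome risk ratio across covariate levels as RR, and a 0.5
     continuity correction on zero cells;
5. top-*k* selection (default 200; 100/500 as sensitivities).

## Propensity scores, weights, balance

The PS model (exposure ~ age + sex + top-k recurrence covariates) is an
L1-penalized logistic regression with seeded 5-fold cross-validated
regularization strength, or XGBoost with fixed seed as a sensitivity.
Scores are clipped to [1e-6, 1 − 1e-6] to preclude infinite weights.
Stabilized weights use the marginal exposure prevalence as numerator
(intercept-only numerator model) and are truncated at the 99th percentile
— upper tail only, so minima are untouched. Balance is checked by the
standardized mean difference in the weighted sample, `|m1 − m0| /
sqrt((v1 + v0)/2)` with weighted moments, maximum over indicator levels
for categoricals; SMD ≤ 0.2 counts as balanced (0.1 as a sensitivity),
with equality passing. Investigator covariates that remain imbalanced are
re-adjusted in the weighted outcome model.

## Multiple outputation

Control sampling is re-randomized R times (seed = base + r; the cohort and
hdPS prioritization stay fixed; per-repetition PS refits are available via
the weight callback). Estimates are pooled as the mean; the pooled
variance is `within − (1 − 1/R)·between` (the finite-R coefficient;
the full-subtraction variant is available), falling back to `within` with
a warning if non-positive. Repetitions that fail estimation are skipped
and counted; more than 20% failures aborts.

## Numerical and design choices

* 95% CIs use the 1.96 normal multiplier throughout.
* All stochastic components take explicit seeds; identical configuration
  reproduces every table and estimate bit-for-bit (float summation order
  aside, which is also pinned by deterministic row ordering).
* Problem sizes used by the test suite and acceptance checks: estimator
  equivalence and immortal-time direction use 50 replicates of n = 3000;
  hdPS deconfounding 50 replicates of n = 2000 with 200 candidate codes;
  outputation coverage 100 replicates of n = 2000 with 20 repetitions;
  calibration checks run at n = 500–600. These sizes give Monte-Carlo
  standard errors small enough for the 2-SE acceptance bands while keeping
  a full run on one CPU in the tens of minutes.
* The acceptance bands themselves (2 Monte-Carlo SEs, coverage 95 ± 5
  points) follow directly from the binomial/normal sampling error of the
  replicate counts, not from tuning.

## Known limitations

* The weighted conditional-logistic pseudo-likelihood treats weights as
  fixed; no correction is made for PS estimation uncertainty beyond the
  sandwich clustering on sets.
* Kaplan–Meier-calibrated inclusion-probability weights for generalizing
  NCC estimates to the source cohort are out of scope, as are PS matching
  or trimming, target-trial emulation, and per-drug-class effects.
* The simulator's single latent confounder is a deliberately simple
  confounding structure; hdPS performance on it should be read as a
  correctness check of the machinery, not a benchmark of hdPS itself.
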