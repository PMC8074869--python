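# Methods

## Problem and data model

The package models a prospective preoperative monitoring design: patients
scheduled for pancreatectomy wear a wrist device for the weeks before
surgery, producing minute-granularity step counts, heart rate and sleep
stages; a clinical characteristics table and 30-day postoperative
complication records complete the dataset. The prediction target is
*failure to achieve a textbook outcome* — a composite of pancreatic
fistula (any grade), bile leak, post-pancreatectomy hemorrhage, any severe
complication (MAGS grade ≥ 3), readmission within 30 days of discharge, and
in-hospital death. A distal pancreatectomy discharged with a drain still
counts as textbook when the drain is out on or before day 4. Nonsevere
(grade 1–2) delayed gastric emptying and "other" events are not in the
listed absence set and therefore do not disqualify; this reading is
deliberate and localized in `outcomes.textbook_outcome`.

Days are segmented at local midnight (timestamps are stored timezone-naive
local, since circadian features need wall-clock time) and held as fixed
1440-slot arrays. The daily **yield** is the fraction of the 1440 expected
heart-rate readings present; the denominator stays 1440 even for partial
first/last monitoring days so yields are comparable. An absent steps cell
with heart rate present is read as 0 steps (a worn device reports zeros);
sleep stages are coded awake=0, light=1, deep=2, REM=3.

## Missing data

Three routes by daily yield: discard at 0%; **data-level** KNN imputation
at ≥ 10%; **feature-level** imputation in between. Data-level: a missing
minute's neighbours are the day's observed minutes, compared by Euclidean
distance on the concatenated (steps, heart-rate) profiles of a ±5-minute
window, with missing entries inside any candidate window padded by the
day's channel mean; the imputed value is the unweighted mean of the
k_data = 5 nearest neighbours. Feature-level: each missing day-feature is
the unweighted mean of that feature over the k_feature = 3 nearest donor
days *of the same patient*, with donor distance computed on the features
the sparse day did observe (donor-pool z-scaled). The "same participant,
same day" description of the original protocol is ambiguous between
cross-feature regression within a day and borrowing across days; the
day-donor reading is implemented and isolated behind
`impute_feature_level` so the alternative could be swapped in. The k
values and window width are configuration, not published values.

Observed values are never modified on any route, and data-level imputation
is idempotent on complete days.

## Features

Per day and channel (steps, heart rate, sleep stages):

* first-order: mean, max, min, moment skewness g₁ and excess kurtosis g₂,
  with the 0/0 constant-series case mapped to 0;
* co-occurrence: the series is quantized into 8 equal-frequency bins
  (values equal to a bin edge stay in the lower bin, so two-valued series
  keep two levels) and the normalized matrix P of (x_t, x_{t+1}) pairs
  yields energy, entropy (bits), correlation (1 in the degenerate σ = 0
  case), inertia, local homogeneity;
* DFA: the mean-centred series is integrated, split into non-overlapping
  windows of 30/40/50/60 minutes, linearly detrended per window, and the
  pooled RMS residual F(n) reported per window length (`dfa_slope` provides
  the multi-scale log–log exponent as a utility — ~0.5 on white noise);
* semantic: sedentary time (observed zero-step minutes), sedentary bouts
  (runs ≥ 10 consecutive zero-step minutes; missing minutes break runs),
  time in bed (first to last recorded sleep minute of the day) and
  sleep-onset latency. Sleep episodes crossing midnight contribute to both
  adjacent days' semantics; since daily features are aggregated to
  mean/variance this split is consistent across patients.

Whole-period rhythm features per channel (steps, heart rate): IS and IV on
60-minute epochs, L5/M10 on contiguous circular hourly windows of the mean
24-h profile, amplitude, relative amplitude (0 when M10 + L5 = 0; IS is
undefined, hence missing, for a constant series), and the fixed-24-h
cosinor via the linear cos/sin parameterization (A ≥ 0, φ ∈ [−π, π),
log-amplitude missing when A = 0).

Aggregation: mean and *sample* variance (ddof = 1; 0 when a single day) of
each daily feature, plus the rhythm block once — the vector dimension is
independent of monitoring length. Clinical categoricals are one-hot encoded
over observed categories (binary fields collapse to one 0/1 column;
unseen categories at transform time become all-zero indicators with a
warning); continuous labs pass through unscaled. Encoding happens at
matrix-build time (the column space must be shared across folds); every
*statistical* fit — median gap fill, scaling, selection, hyperparameters —
happens inside each training fold.

## Modeling and evaluation

Feature selection scores categorical columns by chi-square and continuous
columns by ANOVA F, ranks within each class, and merges by rank with ties
broken by univariate p-value (comparable across the two test families)
then column order; the default budget keeps k = 20 columns. Grid search
uses stratified 3-fold inner CV by AUROC; `REDUCED_GRIDS` holds one-point
grids for simulation studies so no inner loop runs. The gradient-boosted
family is backed by LightGBM (exposing the learning-rate and L1/L2
regularization knobs that matter at n ≈ 48); the other four by
scikit-learn.

LOSO evaluation pools one out-of-fold probability per patient. AUROC is
computed on the pooled probabilities with midrank tie handling (per-fold
AUROC is undefined for single-subject test folds). The decision threshold
is the ⌈0.9·n₊⌉-th largest positive probability — the largest threshold
whose pooled sensitivity meets the 0.9 anchor — and sensitivity,
specificity, precision and F1 are reported at it. The positive class is
failure of the textbook outcome. A precomputed surgical-risk-calculator
column can be evaluated as a no-fit baseline.

Shapley attributions use the sampled-permutation estimator with marginal
background sampling (default: the training cohort as background, 1000
permutations); per permutation the contributions telescope to
f(x) − f(z), so mean attributions satisfy efficiency up to Monte-Carlo
error. An exhaustive 2^d enumeration (`exact_shapley`) serves as the test
oracle at small d.

## Cohort statistics

`chi_square_test` applies the Yates continuity correction exactly when the
table is 2×2 and plain Pearson otherwise; `anova_f_from_summaries`
reconstructs one-way F from per-group (n, mean, SD) with the
population-SD (divisor n) convention. Both conventions are pinned by exact
reproduction of the shipped cohort report: all nine categorical p-values
agree at the printed two decimals (the tobacco table's exact p, 0.44500,
sits on the rounding boundary of its printed .45) and the F statistics
agree to ≤ 0.01.

## Synthetic cohort generator

The generator defines the study conditions used throughout testing:
48 patients, textbook prevalence 28/48, monitoring spans lognormal with
mean 26 days clipped to [6, 153], steps/day lognormal with mean 4162.1 and
SD 4052.6 across patients, heart-rate baselines normal with mean 75.6 and
SD 14.8, daily yield targets normal(0.821, 0.235) truncated to [0, 1] with
a few days forced to 0 and into (0, 0.1) so every imputation route is
exercised.

Per-minute steps are a zero-inflated Poisson process gated by a
patient-specific daytime activity profile (a half-wave cosine bell mixed
with a flat floor; the mixing weight is the patient's activity-contrast
trait and controls relative amplitude). Heart rate is baseline + 24-h
cosine + 0.25 bpm per concurrent step + N(0, 3) noise — the step coupling
gives the data-level imputation genuine cross-channel signal. Nightly sleep
episodes start ~22:30, may spill past midnight, and cycle light/deep/REM
in 10-minute blocks after an exponential sleep latency.

Outcomes are drawn from a logistic model whose linear predictor is
`effect_size` times the standardized mean of the designated signal traits
(default: relative amplitude of the step profile and heart-rate baseline);
the intercept is solved per cohort so the expected failure rate matches
1 − prevalence. Labels are then *materialized* as typed, MAGS-graded event
sets (severe complications with the published type mix, readmissions,
occasional nonsevere fistulae) that the `outcomes` labeler maps back to
exactly the drawn label. Risk-calculator baseline columns are the latent
signal score plus noise, rescaled to the published score means/SDs.
`ground_truth` exposes the generating parameters, including the *effective*
cosinor parameters of the expected heart-rate curve (closed-form projection
of baseline + cosine + activity coupling onto the cos/sin basis), which is
what a cosinor fit on unmasked data should recover.

What the generator does not emulate: the real cohort's joint feature
distribution beyond the published marginals, behaviorally irregular
rhythms (synthetic day profiles repeat, so IS runs higher than the printed
cohort values), device artifacts, and any clinical-feature/outcome
association (clinical columns are null by construction, so clinical-only
models should sit near AUROC 0.5 on synthetic cohorts). Passing tests
therefore demonstrate mechanical and statistical correctness of the
pipeline, not real-data discrimination.

## Validation experiments

The original cohort is not deposited, so the published AUROCs are not
recomputable; two property experiments at the study conditions stand in:

* **Null calibration** — on effect-size-0 cohorts the pooled LOSO AUROC of
  the full pipeline should concentrate near 0.5. Pooled leave-one-out AUC
  is known to be *pessimistically* biased at small n: each patient's fold
  is trained without them, so a patient who by chance resembles the
  positives leaves a less positive-looking training set and receives a
  lower score. The diagnostic therefore uses the KNN family, whose
  neighbour-vote probabilities carry the least fit variance of the five
  (the other families show means of roughly 0.38–0.46 on selection-free
  noise at n = 48). Leakage — the failure mode this screens for — would
  bias AUROC upward in any family.
* **Signal recovery** — with effect size 1.0 on the designated activity
  traits, combined features beat clinical-only in mean pooled AUROC
  (gradient-boosted trees, one-point grid) across 20 cohorts, reproducing
  the qualitative feature-set ordering of the original analysis.

The comparison is deliberately an *ordering*, not an absolute level. For
high-variance learners the self-exclusion coupling is strong at n = 48:
instrumenting one cohort showed models from *other* folds (which saw
patient i in training) rank i perfectly, while i's own fold's prediction
carries a deficit almost perfectly anti-correlated with i's label. This
depresses pooled-LOO AUROC for every feature-set configuration by the same
mechanism, so the combined-vs-clinical difference — in which the bias
largely cancels and only the combined arm carries signal — is the
meaningful quantity, while absolute pooled levels on small null-ish
cohorts sit below the values an independent test set would give. This
matches the published critiques of leave-one-out AUC estimation in small
samples and is a limitation of the evaluation design itself, inherited
faithfully.

Simulation sizes (20 seeds × 48 patients, one-point grids, unmasked series
for the model experiments since imputation has its own benchmark) keep the
full experiment battery to a few minutes while leaving the binomial checks
well-powered.

## Numerical choices and edge cases

Ties in neighbour distances, feature ranks and sorting are broken by
stable order (candidate minute, column position). Degenerate inputs are
mapped, not errored, wherever a convention exists: constant series give
skewness/kurtosis 0, co-occurrence correlation 1, DFA 0, cosinor amplitude
0 with phase 0; IS of a constant series is missing; relative amplitude of
an all-zero profile is 0. Hard errors are reserved for contract
violations: empty series, under-determined fits, days routed against the
yield policy, single-class training folds, zero-margin contingency tables.

## Limitations

Single-site design assumptions (one device cadence, 1440-minute days, no
daylight-saving handling); no multiple imputation or uncertainty
propagation; no spectral features; the distal-drain allowance is an
explicit flag rather than inferred from event data; Table-style real-data
quantities that require undeposited per-patient values (age/BMI tests,
real SHAP rankings) are out of scope.
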