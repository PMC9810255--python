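# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the limitations of the `brainage` package.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Brain-age model

The brain-age regressor is a Gaussian process with

* exponential (Ornstein–Uhlenbeck, i.e. Matérn ν = 1/2) isotropic kernel
  on standardized features: `k(x, x') = σ_f² exp(−‖x − x'‖ / ℓ)`;
* constant mean `c`;
* i.i.d. Gaussian observation noise `σ_n`.

Features are z-scored with training-set means/SDs (constant training
features are rejected — a zero SD cannot be standardized).  The
posterior-mean predictor is the closed form
`f(x*) = c + k*ᵀ (K + σ_n² I)⁻¹ (y − c)`.

**Hyperparameter estimation.** `(log ℓ, log σ_f², log σ_n²)` maximize the
log marginal likelihood by L-BFGS-B with multiple deterministic starts
(median pairwise distance × {½, 1, 2} for ℓ; target variance scalings for
σ_f², σ_n²).  The constant mean is profiled out: given the other
parameters its generalized-least-squares estimate
`c = (1ᵀA⁻¹y)/(1ᵀA⁻¹1)`, `A = K + σ_n²I`, is closed-form, so the search
space stays three-dimensional.  Box bounds in log space keep the
factorization conditioned (σ_n² ≥ 10⁻⁸ · var(y)).

**Numerics.** A relative jitter of 10⁻⁸·σ_f² is added to the kernel
diagonal by default (standard GP practice, invisible at reported
precision); it is configurable, and `jitter=0` reproduces the textbook
equations exactly — the oracle tests use that setting.  A singular kernel
matrix (duplicate inputs with zero noise and zero jitter) raises an error
that advises adding jitter rather than silently regularizing.

**Splits and cross-validation.** Controls are split 7:3 into training and
hold-out sets; the training size is `floor(ratio·N)` evaluated in floating
point, the convention under which 330 controls at ratio 0.7 yield the
conventional 230/100 split.  Cross-validation uses uniformly random
near-equal folds (not age- or sex-stratified).  Repeated CV reshuffles the
folds each repeat (repeat *r* seeds its fold permutation with
`SeedSequence([seed, r])`), computes MAE and Pearson *r* on the pooled
out-of-fold predictions of each repeat, and summarizes the repeat
distribution as mean ± SD with a normal-approximation 95% CI
(mean ± 1.96·SD/√R).  The default is 10 repeats — CV repetition only
narrows the CI of the summary, so the package default favors a small
problem size; the repeat count is a parameter for anyone who wants the
thousand-repeat variant.

**Training-set metrics use out-of-fold predictions; hold-out and patient
predictions use the model refit on the full training set.**  Whether the
reference analysis used out-of-fold or refit predictions for its
training-set metrics is not stated anywhere we could check; out-of-fold
avoids optimism and is documented here as our choice.

## Age-bias correction

Raw brain-age predictions regress toward the training mean: the young are
over-predicted and the old under-predicted.  On the training set's
out-of-fold predictions we fit OLS

    brain age = α · Ω + β        (Ω = chronological age)

and correct every subsequent prediction by

    corrected = raw + [Ω − (α·Ω + β)].

Algebraic consequences, asserted numerically in the tests: on the fitting
set the OLS of corrected brain age on age is the identity (slope 1,
intercept 0), the mean BAG is zero, and BAG is uncorrelated with age.  The
correction is fitted **once per modality on control training data and then
frozen**.  It is never refitted on patients: a patient-specific refit
would absorb exactly the disease signal the BAG is meant to expose.  Only
the linear (two-parameter) correction is implemented.

## Synthetic cohort generator

The generator is the package's substitute for confidential clinical
tables; its defaults are the study conditions every test and the
acceptance script run under.

**Latent structure.**  Each participant has a latent brain age *b*:
`b = age` for controls, `b = age + δ_m(duration)` for patients, where
`δ_m` is the modality's deviation profile.  A fraction (default 0.8) of
each modality's features carry the signal with loading
`slope · U(0.5, 1.5)` (slope −1 feature-unit/year by default: structure
declines with age); the rest are pure noise.  Feature *j* of subject *i*
is `intercept_j + w_j·b_i + ε`, ε i.i.d. Gaussian with per-modality SD.
Features are conditionally independent given the latent age — the
reference study publishes no feature covariances, so anything richer would
be invented structure (see Limitations).

**Deviation profiles** (brain-age years as a function of illness duration
*d*, chosen to reproduce the qualitative trajectory findings — thickness
deviating strongly from onset, volume accelerating roughly two decades
in, FA null):

| modality  | profile                              | shape |
|-----------|--------------------------------------|-------|
| thickness | `6 + 1.5(1 − exp(−d/8))`             | large onset offset, plateau ≈ 7.5 y |
| volume    | `1.5 + 0.05d + 0.7·max(0, d − 20)`   | moderate onset offset, late acceleration |
| fa        | `0`                                  | null at all durations |

The raw curves cross near *d* ≈ 26 y; because the volume model is the most
accurate (smallest BAG spread), the *effect-size* crossover lands earlier,
around two decades after onset.  Profiles are configurable callables; the
defaults are continuous in duration.

**Demographics.**  Control ages are drawn piecewise-uniformly from the
reference cohort's decade-bin age histogram (92/50/55/68/58/3/4 of 330
across 20–29 … 80–84), giving mean ≈ 43.5, SD ≈ 15, and an age-balanced
case-control comparison.  Patient illness durations come from the
reference duration histogram (10/28/44/46/66 of 194 across <1 / 1–5 /
6–10 / 11–20 / >20 years, upper edge 38); patient age is onset + duration
with onset ~ N(27.7, 6) truncated to the jointly feasible range, which
enforces adult onset (`duration ≤ age − 18`) and reproduces the reference
patient age distribution (≈ 43 ± 12).  Sex is assigned as fixed
enrollment counts (56.2% / 60.9% female in patients / controls),
education, MMSE, PANSS subscales (total = positive + negative + general)
and CPZ dose as clipped Gaussians with the reference means/SDs; ~17% of
patients lack a CPZ record.  Sex has no effect on features, and PANSS/CPZ
are independent of the planted deviation by default; a
`clinical_bag_coupling` knob couples symptom scores to the deviation for
power experiments.

**Feature noise** (SD 25 / 45 / 35 for volume / thickness / FA) was set so
the three models' accuracies order the same way as in the reference
analysis (volume best, thickness worst).  Because controls' latent brain
age equals chronological age *exactly*, averaging over ~50 informative
features recovers age more precisely than real MRI features allow: at
these conditions hold-out MAE is ~3–4 years and *r* ≈ 0.94–0.97, tighter
than is realistic.  Passing tests therefore demonstrate correct recovery
of planted structure, not realistic effect or error sizes.

## Windows, matching, outliers

Regular windows `[s, s + width)` start at `s = 0, step, 2·step, …` while
the inclusive upper label edge stays below the tail-merge start (defaults:
width 5, step 1, merge at 31), then one merged tail window covers the
longest durations; with the defaults and a 38-year maximum that is 27
regular windows (0–4 … 26–30) plus 31–38, 28 in total.  Windows overlap
by design, so a patient contributes to up to `width/step` windows.  The
regular grid deliberately stops so that no regular window straddles the
merge boundary; the boundary is configurable.

Matching draws one hold-out control per window patient: within sex,
minimal |age difference| among not-yet-used candidates, patients visited
in random order, ties broken at random (a uniformly-random-within-caliper
mode is also provided).  Sampling is without replacement within a window
and with replacement across windows, matching per window rather than once
overall; the mean absolute age difference is recorded on the window.

Patient BAGs are screened once per window per modality with Tukey fences
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; Q1/Q3 use numpy's linear-interpolation
percentile convention (the boxplot literature does not fix one; the
convention is documented here and pinned by tests).  The screen is
skipped, with a warning, below 4 values.  Matched controls are not
screened by default.

## ANCOVA and inference

Per window and modality the model `BAG ~ diagnosis + age + sex + MMSE +
education` is fitted by OLS (statsmodels).  For a two-level factor the
partial (Type-III-equivalent) F of diagnosis equals the squared t of its
coefficient, which is how it is computed; the equality with an explicit
full-vs-reduced residual-sum-of-squares computation is asserted by test.
`partial η² = SS_group/(SS_group + SS_error)`, with both sums of squares
stored so the ratio is recomputable.  Sex enters as a 0/1 indicator; F and
η² are invariant to the coding (asserted by test).  Covariates that are
constant or collinear within a window (e.g. sex in a single-sex window)
are dropped and the reduction recorded.  P-values use F(1, n − p); no
small-sample corrections.

The per-test threshold is Bonferroni `family_alpha / m`, default 0.05/5 =
0.01.  How overlapping windows should be grouped into multiplicity
families is genuinely underdetermined (adjacent windows share most of
their subjects); `m` is therefore a configuration parameter whose default
reproduces the 0.01 threshold.

Demographic tables report the independent two-sample t-test in **both**
pooled and Welch variants — the reference demographic table is internally
consistent with different variants on different rows, so the package
prints both — and Pearson's chi-square without continuity correction.
BAG–clinical correlations (PANSS total and subscales, CPZ dose) use
Pearson *r* with pairwise deletion, so the CPZ cell's n counts only
patients with a recorded dose.

## Design decisions that were genuinely open

* **Windows too small to analyze** (fewer than 3 subjects per arm after
  outlier screening, or a degenerate design) are retained in the results
  table flagged `analyzed = False` rather than aborting the run.
* **Greedy vs. pure-random matching**: "randomly selected, age- and
  sex-matched" underdetermines the algorithm; greedy nearest-age with
  random tie-breaks honors both constraints and is the default, with the
  caliper mode as the alternative.
* **One bias correction per modality, fitted on training out-of-fold
  predictions** — not per dataset, not on patients.
* **Percentile convention, split convention, fold assignment**: documented
  above; each is pinned by a test so a change is visible.

## Limitations

* No spatial structure, no feature covariance beyond the shared latent
  age, no site/scanner effects, no longitudinal repeated measures: the
  generator validates the pipeline's statistics, not its robustness to
  real MRI artifacts.
* Controls' latent brain age is exactly chronological age, so
  individual-level biological variation in healthy aging is absent and
  synthetic accuracies are optimistic (see above).
* Effect sizes below the noise floor of a 5-year window (the early-course
  volume deviation at the default conditions) are detected as a trajectory
  shape but not as per-window significance — a faithful property of the
  design, not a bug: overlapping 5-year windows at n ≈ 20–50 have limited
  power for sub-2-year BAG shifts.
* The GP is the only regressor; the fitting interface is pluggable but no
  ridge/forest baselines are shipped, and no per-subject uncertainty is
  reported.
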