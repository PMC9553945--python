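# Methods

This note documents the generative model behind the synthetic cohorts,
the cleaning and evaluation protocols, and the numerical and design
choices made where more than one defensible option existed.

## The estimation problem

Both model families estimate the conditional probability
p(y = 1 | x) of developing diabetes within three years of a baseline
health checkup, from d = 16 predictors: eight continuous (BMI, SBP, TG,
HDL-C, LDL-C, ALT, HbA1c, age) and eight categorical (sex, smoking,
anti-hypertensive and anti-dyslipidemia drug use, dichotomized urinary
protein, and history of heart disease, stroke and renal failure).

* **Logistic regression** (`LogisticRisk`): σ(w·x + b) with continuous
  predictors standardized on the training data (the same scaling is
  reused on test data). Fitted by unpenalized maximum likelihood with
  L-BFGS under a gradient-norm tolerance of 1e-8 (up to 500
  iterations). A gradient-based stopping rule is used deliberately:
  when a rare indicator perfectly predicts one class, the MLE sits at
  the boundary — the likelihood flattens while that weight drifts, so a
  parameter-change rule (classic Newton) never triggers even though the
  fit, its predictions and the remaining coefficients are all
  well-defined. Genuine perfect separation (all training points
  correctly classified with diverging weights, or a vanishing training
  Logloss) raises `PerfectSeparationError` instead of silently
  returning huge weights. The fitted object exposes coefficient
  standard errors and a `summary()` table; the standard error of a
  boundary coefficient is reported as NaN.
* **Gradient-boosted trees** (`BoostedTreesRisk`): an additive ensemble
  of decision trees grown stagewise on the Logloss objective
  (LightGBM), probability output through the sigmoid. Boosting stops
  when validation Logloss fails to improve for 30 consecutive rounds
  (cap 1000 rounds); when no validation set is supplied, a stratified
  10% carve-out of the training data serves as one — the protocol never
  touches the test set during training. Runs are made reproducible with
  a fixed seed, single-threaded deterministic training and row-wise
  histogram construction.

Hyperparameter tuning (`tune_gbdt`) is a seeded random search over the
seven standard knobs (number of leaves, feature fraction, bagging
fraction and frequency, minimum leaf size, L1/L2 regularization), each
trial scored by mean out-of-fold Logloss under stratified 5-fold CV
with early stopping inside every fold. Random search was chosen over a
sequential model-based optimizer for transparency and exact
reproducibility; with the budgets used here (tens of trials) the two
are practically indistinguishable on a 7-dimensional space. Counts and
regularization strengths are sampled log-uniformly, fractions
uniformly.

## Evaluation metrics

Predictions on [0, 1] are binned into M equal-width intervals
[(m−1)/M, m/M), the last bin closed at 1 so p = 1 is assigned; ties at
bin edges go to the upper bin. The reliability diagram plots the
per-bin observed positive fraction ȳₘ against the per-bin mean
prediction p̄ₘ, and

    ECE = Σₘ (Nₘ/N) · |ȳₘ − p̄ₘ|,

with empty bins contributing nothing. M defaults to 10 (exposed as
`--bins`/`n_bins` and recorded in all outputs); equal-width rather than
equal-frequency bins are used throughout. Logloss is the mean negative
log-likelihood in nats with predictions clipped to [1e-15, 1 − 1e-15]
before the logarithm. AUC is computed in the tie-aware Mann–Whitney
form (half credit per tied pair), which coincides with trapezoidal ROC
integration; the test suite cross-checks both ECE/Logloss/AUC against
brute-force oracles and AUC against an independent ROC implementation.

## Protocols

* **Cross-validation**: stratified k-fold (k = 5) preserving the
  positive fraction per fold; logistic regression re-estimates its
  standardization on each round's training portion. Metrics are
  aggregated as mean ± SD over folds.
* **Sample-size sweep**: one stratified 80/20 split is frozen for the
  whole experiment. For each training size, subsamples are drawn
  without replacement from the 80% pool (100 repeats by default; draws
  are unstratified to match simple random sampling, with a stratified
  option), each model is trained on the subsample and scored on the
  common 20% test set. Cells whose subsample is single-class, or whose
  fit fails (e.g. perfect separation on a tiny draw), are skipped and
  logged rather than aborting the protocol; the skip count is part of
  the result. Boosted-tree hyperparameters are tuned once per size on
  the first resample and reused across that size's repeats (per-repeat
  tuning at 100 resamples × many sizes would dominate the runtime for
  no qualitative change; a per-fold option exists for CV).
* **Aggregation**: mean and population SD (denominator n), recorded in
  the output metadata.

All protocols are pure functions of (cohort, configuration, seed); the
seed feeds a hierarchical `SeedSequence` with one substream per stage.

## Synthetic cohort generator

The generator emulates the *cleaned-cohort* statistics of a large
insurance health-checkup population together with the raw-data defects
its selection funnel removes.

**Marginals.** Continuous labs are drawn from quartile-matched
log-normal laws: the symmetric closed form uses exp(μ) = median and
σ = ln(Q3/Q1)/(2·z₀.₇₅). Because printed quartiles are not always
log-symmetric (HDL-C's are skewed the other way), sampling actually
uses a quartile-exact two-piece variant with separate σ below and above
the median; it reduces to the single-σ law when the quartiles are
log-symmetric, and reproduces all three printed quartiles to well
within 1% at n = 1e5. Age — bounded and asymmetric — uses an
integer-discretized equal-mass two-piece normal on [40, 95]. Binary
predictors are Bernoulli at the published prevalences; urinary protein
is drawn over its five dipstick levels (−, ±, 1+, 2+, 3+) with the
published 5.3% positive mass split across 1+/2+/3+ in typical dipstick
proportions. An optional Gaussian copula imposes rank correlation
between continuous predictors; the default is independence, since the
published tables carry no joint structure.

**True risk.** The log-odds are linear in the standardized continuous
predictors (standardization by the theoretical generative moments) and
the 0/1 categorical indicators, plus a configurable nonlinear part.
The default linear coefficients are set loosely from the published
positive/negative group contrasts (HbA1c dominant at 0.9 per SD, then
treatment flags, adiposity, age; female protective). The default
nonlinear part — a hinge of 1.3 on standardized HbA1c above +1 SD
(~5.9%, the pre-diabetic range where risk accelerates), a 0.4 hinge on
BMI, and a 0.15 age×BMI product — deliberately misspecifies a purely
linear logit while staying clinically interpretable; this is what gives
the flexible model headroom and produces the learning-curve crossover.
Setting the nonlinear coefficients to zero (`nonlinear=False`) yields a
world in which logistic regression is exactly correctly specified —
used by the coefficient-recovery tests. The intercept is calibrated by
Brent root-finding (auto-widened bracket) so the mean true risk over
the drawn covariates hits the target prevalence of 5.727%.

**Follow-ups.** Outcome labels are drawn first (Bernoulli at the true
risk), then 1–3 follow-up visits inside the 3-year window are
back-filled to agree: every positive receives at least one visit
meeting the diagnostic rule (FPG ≥ 126 mg/dL, HbA1c ≥ 6.5%, or
anti-diabetic drug self-report — mixed 50/35/15), and no visit of a
negative meets it. Generating labels first keeps prevalence under the
risk model's exact control.

**Pathologies.** Injected independently of risk, at rates sized so the
funnel retains a fraction comparable to the published flowchart (~34%):
sex/birthday inconsistency 1e-5; no follow-up within the window 0.487
(implemented by shifting all visits past day 1095); baseline diabetes
history 0.18 plus 0.048 missing-history; per-predictor missingness
0.006 and sentinel codes (0, 999.9) at 0.002 on continuous labs.
Because pathologies are independent of the outcome, the cleaned
prevalence stays near the calibrated target; the two-sided outlier trim
removes slightly more high-risk than low-risk records (the HbA1c upper
tail), costing roughly 0.1 percentage point — well inside the fidelity
tolerance used in the tests.

## Cleaning pipeline decisions

* "Within 3 years" means a follow-up offset ≤ 1095 days.
* The variable screen drops columns with missing rate > 10%, then a
  forced drop list (DBP, AST, γ-GTP, UG) standing in for a
  multicollinearity screen whose outcome, not procedure, is known.
* The outlier rule is read as per-variable two-sided trimming at the
  0.0005 / 0.9995 empirical quantiles (linear interpolation), computed
  after missing/sentinel removal so sentinel codes cannot pollute the
  quantiles, with participant-level exclusion on strict inequality
  (values tied with the quantile are kept). Quantiles are estimated on
  the whole selected population, not within subgroups.
* Missing values are excluded, never imputed.
* The 16-predictor column order is fixed
  (BMI…HbA1c, age, sex…MH_renal) so coefficients are comparable across
  runs.

## Problem sizes in the shipped tests

The suite exercises the protocols at desk scale: marginal fidelity at
n = 1e5, coefficient recovery at n = 50,000 × 100 replicates, and the
learning-curve comparison on a 60,000-participant nonlinear cohort with
sizes 1,000–30,000, 20 repeats and a reduced tuning budget. These sizes
keep the full suite in the minutes range while leaving the qualitative
conclusions (calibration improving with data; the flexible model
overtaking the misspecified linear one at the largest sizes)
reproducible.

## What passing tests do and do not show

The generator matches published *marginal* summaries and prevalences;
it does not estimate the real joint distribution, the true effect
sizes, insurer-switch dynamics, age-computation error, or calendar
time beyond a follow-up offset. Its true-risk defaults are declared
stand-ins, not estimates of the real data-generating process.
Consequently the pipeline reproduces the *qualitative* phenomena —
calibration and discrimination improving with sample size, and the
flexible model overtaking a misspecified linear model once training
data is plentiful — but the published headline metric values, computed
on the non-shareable cohort, are not reproducible here even in
principle, and the bin count behind the published ECE values is
unreported, so no numerical ECE comparison is attempted. Known further
limitations: ECE with equal-width bins is dominated by the low-risk
bins under class imbalance (high-probability bins carry little weight);
boundary MLEs at small training sizes inflate logistic-regression
Logloss variance on rare indicators; and the Hosmer–Lemeshow test and
post-hoc recalibration (Platt/isotonic) are deliberately out of scope —
the pipeline evaluates raw model outputs.
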