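# Methods

## The forecasting model

For each assessment of a subject (a *sample*), the package forecasts the
number of falls the subject will report at the following study wave as a
full probability distribution, not a point score. The predictive
distribution is negative binomial (NB2) with mean μ and dispersion θ:

    P(Y = y | μ, θ) = Γ(y+θ) / (Γ(θ) y!) · (θ/(θ+μ))^θ · (μ/(θ+μ))^y,

with variance μ + μ²/θ. As θ → ∞ the distribution tends to a Poisson with
the same mean; small θ means strong overdispersion. The two parameters are
estimated in sequence:

1. **Mean.** μ = exp(β₀ + xᵀβ) from an L1-penalized (Lasso) Poisson
   regression over the screened covariate block. The penalty performs
   variable selection and shrinkage simultaneously; the set of covariates
   with nonzero coefficients is the *active set*.
2. **Dispersion.** Given the fitted means, θ is the maximizer of the NB
   log-likelihood Σᵢ log P(yᵢ | μᵢ, θ) over log θ in [10⁻³, 10⁶] (1-D
   bounded optimization). If the likelihood is maximized at the upper
   bound — no overdispersion beyond the Poisson — the bound is returned
   and flagged; predictions remain NB-parameterized for uniform handling.
   The estimator agrees with R's `MASS::theta.ml` to ~10⁻⁸ on test
   fixtures.

## Penalized fitting

The Poisson Lasso minimizes

    −(1/N) Σᵢ [yᵢ ηᵢ − exp(ηᵢ)] + λ ‖β‖₁,   ηᵢ = β₀ + xᵢᵀβ,

with the intercept unpenalized and covariates standardized to zero mean /
unit variance internally (constant columns get coefficient zero). The
solver is glmnet-style: outer iteratively-reweighted least squares with
working response z = η + (y−μ)/μ and weights μ; inner coordinate descent
with soft-thresholding; warm starts along a 100-point log-spaced grid from
λ_max = maxⱼ |(1/N) Σᵢ xᵢⱼ(yᵢ−ȳ)| down to 10⁻³ λ_max. Tolerances:
coordinate step 10⁻⁷ on the maximum coefficient change, outer loop 10⁻⁶
relative on the penalized objective; caps 10⁴ coordinate sweeps and 100
outer iterations per grid point. At λ = 0 the fit agrees with an
unpenalized Newton solver (statsmodels GLM) to < 10⁻⁴ per coefficient. If
all outcomes are zero the intercept is clamped at log(10⁻⁸) with a
warning.

**Model-size constraint.** A cap *n* on the number of covariates is
enforced by path truncation: return the smallest-λ grid point whose
active-set size is ≤ n with all larger-λ points also ≤ n. Because the
active set grows in jumps along the grid, the fitted models typically use
fewer covariates than the cap allows — the mean active count sits below
*n*, which is the behavior the accuracy-parsimony analysis reports.
Exact Lasso paths can drop and re-admit variables; the constraint is
checked per grid point and the truncation takes the longest all-compliant
prefix.

## Screening and imputation

Covariates are screened before modeling, in order of precedence:
categorical with more than two levels → dropped; missing **strictly** more
than 50% of values → dropped; imputation non-convergence (below) →
dropped per fold. Remaining binary categoricals are recoded 0/1 by sorted
level order.

Missing values in kept covariates are assigned by deterministic regression
rules on three complete predictors associated with health status: age,
sex, and time to walk 7 m at usual pace. Continuous covariates use
ordinary least squares; binary covariates a logistic fit thresholded at
probability 0.5. "Did not converge" is operationalized as: fewer than 10
observed training rows, singular normal equations, logistic separation
(coefficient blow-up past ±30) or more than 100 Newton iterations, or a
binary covariate constant where observed. Rules are fitted on training
rows only, so each cross-validation fold carries its own imputation model
and held-out data cannot leak into it. Imputation is a deterministic
assignment, not a stochastic draw — the simplest reading consistent with a
three-predictor imputation model; no chained equations or multiple
imputation.

## Cross-validation design

Fitting and evaluation use 10-fold cross-validation with *subject
grouping*: subjects are shuffled by seed and dealt round-robin to folds,
and every sample of a subject lands in the same fold, so a model is never
evaluated on a person it has seen. Within each outer training set:

- the penalty λ is selected by an inner 5-fold subject-grouped
  cross-validation minimizing mean Poisson deviance (the source analysis
  does not state how λ was chosen; nested CV is this package's own
  choice, matching common glmnet practice). Under a model-size cap, the
  selected grid point is further truncated by the cap rule above.
- The inner CV reuses the outer fold's imputed training data rather than
  re-fitting imputation per inner split; imputation leakage across outer
  folds — the one that would bias the reported performance — is fully
  avoided, and re-imputing per inner fold would multiply runtime by ~6
  for a second-order refinement of λ selection only.
- θ is estimated from the outer training folds using the in-sample means
  of the final fit (whether the original analysis used in-sample or
  held-out means is unstated; in-sample is the simplest reading).

Every sample therefore receives exactly one out-of-fold NB predictive
distribution; these, plus the benchmark columns, feed the evaluation.

## Evaluation

- **Outcomes.** *Faller*: ≥ 1 fall at follow-up; *multiple faller*: > 1.
- **Discrimination.** Mann–Whitney AUC (ties half credit) with DeLong
  variance (midrank formulation) for 95% CIs, and DeLong tests for paired
  ROC curves comparing each benchmark against the model mean and the
  external risk score. Two-sided p-values, no multiplicity correction.
  Negatively health-oriented scores (gait speed, SPPB) are sign-flipped
  before ROC analysis. Samples missing a benchmark are excluded pairwise.
- **Reliability diagram** adapted to counts: samples stable-sorted by
  (μ, subject id), split into deciles of near-equal size; per bin the mean
  predicted rate, mean observed count, and a normal-approximation 95% CI
  half-width 1.96·sd(y)/√n (the error-bar construction is not specified
  in the source; this is the package's choice).
- **Marginal calibration**: for each count k up to max(observed)+5 (≥ 9),
  the observed number of samples with Y = k against Σᵢ Pᵢ(Y = k);
  error = predicted − observed.
- **PIT** for count data, non-randomized: the conditional PIT is 0 below
  F(y−1), linear on [F(y−1), F(y)], 1 above; the mean over samples is
  evaluated at u = j/J and differenced into J = 10 bins (bin count not
  stated in the source; 10 is the standard default). A flat histogram
  indicates neutral dispersion; a U shape under-dispersed forecasts —
  which is what Poisson (θ at bound) forecasts produce on overdispersed
  counts. Observations with zero predictive probability degrade to a step
  and emit a warning.
- **MSE** between observed counts and predicted rates μ.
- **Representative distributions**: predictive pmfs of the samples at the
  2.5th/10th/90th/97.5th percentiles of the risk score (nearest-rank),
  against the pooled observed count distribution.

## Accuracy–parsimony and learning curves

The parsimony sweep repeats the full cross-validated pipeline for each cap
n (default 1..40), reusing one fold assignment so curves differ only
through the constraint, and records mean active-set size, AUCs, and MSE.
The learning curve thins each outer training set to a fraction of its
subjects (subject-level, preserving grouping; test folds stay full) and
averages metrics over replicates.

## The synthetic cohort generator

No real cohort ships with the package; the generator produces tables with
the structure the pipeline assumes, with known ground truth. Defaults
describe a community cohort of older adults:

- 1000 subjects, 4 waves 3 years apart, 15%/wave dropout; baseline age
  uniform on [62, 93] with samples under 65 excluded, as are samples with
  no follow-up (so up to 3 outcome-bearing samples per subject).
- Outcome: falls at the next wave ~ NB(μ, θ), log μ = log 0.42 + xᵀβ.
  The intercept matches a typical community fall rate of 0.42
  falls/(person·year); θ = 2 is moderate overdispersion, chosen because
  the source does not report its fitted dispersion and fall counts are
  markedly overdispersed — distinct enough from Poisson for the PIT
  diagnostics to have something to detect.
- 1000 covariates: 30% binary, 5% categorical with 3–5 levels (present to
  exercise the multilevel screen), the rest standard normal, i.i.d. by
  default with an optional equicorrelation knob; 25 informative continuous
  covariates with coefficients ±0.15 (alternating sign), echoing the
  ~20–30-variable plateau and AUC ≈ 0.7 regime of the source analysis.
  Real geriatric-assessment variables are correlated; independence is a
  deliberate simplification — a green selection test here does not
  establish behavior under collinearity.
- Missingness: covariate-wise i.i.d. (MCAR) at rates uniform on [0, 0.3],
  with 5% of non-multilevel covariates forced to rates in [0.55, 0.85] to
  exercise the missingness screen. age/sex/walk-time are always complete.
- Benchmarks tied loosely to the latent rate: fall history is an
  independent NB draw with the same μ capped at 9; gait speed is a noisy
  decreasing function of log μ clipped to [0.2, 2.0] m/s; SPPB a rounded
  noisy transform of gait speed clipped to 0–12; the external risk score
  a noisy 1 − exp(−μ), i.e. roughly the probability of ≥1 fall. The walk
  time is 7 m / gait speed. This reproduces the qualitative ordering
  (model ≥ simple indicators, multiple-faller AUCs ≥ single-faller AUCs)
  but not any real tool's calibration.

A single integer seed drives one random stream for all draws; generation
is bit-reproducible.

## Numerical notes and limitations

- NB pmf/cdf are delegated to `scipy.stats.nbinom` (log-space internally).
- Decile ties in the reliability diagram are resolved by the stable sort,
  so bins have near-equal sizes even when scores tie heavily.
- The DeLong test degenerates when the variance of the AUC difference is
  zero: identical scores return p = 1; otherwise it is an error.
- Reported cross-validated AUCs on small synthetic cohorts are noisy;
  the test suite asserts orderings as medians over seeds, not per run.
- The generator emulates structure, not any study's marginals or
  inter-wave correlations; absolute AUC/MSE values from synthetic runs
  are not comparable to published cohort results.
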