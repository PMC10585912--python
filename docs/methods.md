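# Methods

## The problem

Estimating the effect of a *cumulative* exposure over several follow-up
waves — e.g. repeated exposure to psychosocial stressors at work on
end-of-follow-up ambulatory blood pressure — is complicated by
exposure–confounder feedback: time-varying covariates such as smoking or
body-mass category can be affected by past exposure while also
confounding future exposure. Standard regression then has no correct
adjustment set (adjusting for the time-varying covariates blocks part of
the effect; not adjusting leaves confounding), which motivates marginal
structural models (MSMs) and their estimators. Comparing those
estimators fairly requires simulated data that (a) resemble a real
cohort and (b) have a knowable truth. Plasmode simulation achieves both
by *estimating* the data-generating equations from an input cohort and
then simulating from them.

## Data model

One row per subject with time-ordering (L₁, A₁, L₂, A₂, …, L_K, A_K, Y):
covariates L_t precede the binary exposure A_t within each wave; Y is a
single continuous outcome. Missing data are rejected at validation
(exclude or impute upstream). Categorical level sets are frozen at
validation so that design matrices are identical across resampled
replicates even when a replicate drops a rare level.

For K = 3, exposure histories are summarised into five cumulative
categories — never (000), intermittent (010, 101), cessation (100, 110),
onset (011, 001), chronic (111) — and the MSM is

E[Y^ā] = γ₀ + γ₁·intermittent + γ₂·cessation + γ₃·onset + γ₄·chronic.

This mapping is hard-coded for K = 3 as published; other K default to a
saturated one-category-per-regime coding, and arbitrary regime maps are
accepted. The identifying assumptions are the usual three: sequential
exchangeability given measured history, positivity
(0 < P(A_t = 1 | history) < 1), and consistency.

## Plasmode generation

The joint law factorises as
f(Y | Ā, L̄) · ∏_t f(L_t | Ā_{t−1}, L̄_{t−1}) · f(A_t | Ā_{t−1}, L̄_t).

**Parametric algorithm.** One regression per factor is fitted to the
input cohort — logistic for binary targets, baseline-category
multinomial logit for categorical targets, linear with normal errors for
continuous targets — using main terms over the full time-admissible
history by default (predictor subsets are accepted for parsimony). Each
replicate resamples m rows' wave-1 covariates with replacement (m < n
recommended; time-fixed baseline covariates travel with L₁) and then
draws A₁, L₂, A₂, …, Y sequentially from the fitted conditionals.
Numerical choices: linear-model residual SDs use denominator n − p
(recorded in the fitting log); multinomial draws are single categorical
draws from the fitted class probabilities; fitted Bernoulli
probabilities are used as-is, with no truncation, so that the generated
law is exactly the fitted law and the counterfactual truth below is
coherent with the replicates — positivity problems are allowed to
surface in estimation, where they belong.

**Nonparametric algorithm.** The same factors are fitted with random
forests (classification for categorical targets, regression for
continuous ones; defaults 500 trees, minimum leaf 5, √p
variables-per-split for classification and p/3 for regression, all
recorded in the manifest). Generation draws categorical values from the
forests' predicted class probabilities and continuous values as the
forest prediction plus one draw from the pool of out-of-bag residuals —
a choice that makes the generated conditional law explicit and reusable
by the counterfactual pass. Exposure forests are defined for waves 2..K;
wave-1 exposure is retained from the resample by default (an optional
A₁ forest on the wave-1 covariates supports the alternative), since
both readings of "keep only L₁, though A₁ may be retained" are
legitimate.

**Counterfactual truth.** For each subject's observed L₁ and each regime
ā ∈ {0,1}^K, later covariates are simulated from the fitted covariate
models with the exposures *fixed* at ā (never drawn), and Y^ā from the
fitted outcome model, giving n × 2^K stacked rows per pass. The true MSM
parameters are the OLS coefficients of Y^ā on the category dummies of
this stacked dataset. Because categories pool regimes, the truth is the
*unweighted* pooled mean over the regimes in a category — what the
stacked regression computes — not a frequency-weighted average of
per-regime effects; this matters when effects differ within a pooled
category. Monte Carlo SEs come from between-pass variation (passes ≥ 2)
or subject-level cluster-robust variances (single pass), and are always
reported so downstream bias is judged against the truth's own
uncertainty.

## Estimators

All estimators regress on the cumulative-category dummies; working
models default to main terms over the full admissible history and can be
restricted (to stage misspecification) or saturated (for exact
small-sample identities).

* **Stabilized IPTW.** sw_i = ∏_t P(A_t = a_ti | Ā_{t−1}) / P(A_t = a_ti
  | Ā_{t−1}, L̄_t), both models logistic; weighted least squares of Y on
  the dummies with HC0 sandwich SEs treating weights as fixed. Optional
  symmetric percentile truncation of the weights is applied after
  computation and logged. A fitted probability of exactly 0/1 at an
  observed value raises a positivity error.
* **Sequential g-computation.** Fit E[Y | Ā, L̄]; predict at Ā = ā
  (Q_K); recursively regress Q_{t+1} on (Ā_t, L̄_t) and predict at ā_t
  down to t = 1; average Q₁. MSM coefficients come from stacking the
  per-subject Q₁ values over regimes — a saturated one-way design, so
  the implementation uses the equivalent closed form (pooled category
  means). SE = SD over 50 nonparametric bootstrap resamples of subjects
  by default (1000 is the single-dataset convention); percentile CIs
  optional.
* **TMLE.** The same recursion with a targeted update at each step:
  Q*_t = Q_t + ε·H_t with clever covariate H_t = I(Ā_t = ā_t) / ∏_{s≤t}
  g_s, ε the offset-regression coefficient of the current target on H_t.
  The regression target at step t is the previous step's *fluctuated*
  Q*_{t+1} (Y at t = K) — the standard sequential-regression
  convention. Setting every ε to 0 reproduces g-computation exactly (a
  tested identity). Two SE methods: the empirical efficient influence
  curve (default for single-dataset use), and bootstrap-SD. The IC
  variance estimates the *nonparametric* efficiency bound; when a
  correctly specified parametric outcome model lets the estimator beat
  that bound, the IC SE overcovers (we measured SE/SD ratios of 1.2–2.2
  in the parametric scenario), so the simulation harness uses
  bootstrap-SD(50) for TMLE, mirroring its treatment of g-computation.
  The continuous-outcome fluctuation is linear with an offset (no logit
  bounding of Y).
* **Standard regressions.** OLS of Y on the dummies plus either baseline
  covariates only or baseline + time-varying covariates, model-based
  SEs — the two traditional comparators whose feedback-induced bias the
  framework is designed to expose.

On one-wave discrete data with saturated working models, IPTW,
g-computation, TMLE and brute-force standardization coincide to
numerical precision; this is the suite's strongest correctness anchor.

## Simulation harness

`run_study` spawns one child seed stream per replicate before any work
starts, so results are bit-identical for a fixed master seed regardless
of parallelism; estimator failures are recorded and counted, never
silently dropped, and metrics are computed on successes with the count
displayed. Metrics per estimator × coefficient: bias, SD (ddof 1), RMSE,
and 95%-CI coverage, with Monte Carlo SEs SD/√J, SD/√(2(J−1)) and
√(p(1−p)/J). The identity RMSE² = bias² + SD²·(J−1)/J holds exactly and
is asserted in tests. Coverage is always assessed with estimate ±
1.96·SE intervals.

## The synthetic fixture cohort

The motivating cohort is private, so `fixture.default_design()` supplies
a stand-in with the same structure: n = 1576 subjects; baseline age
~ N(41, 9²) years, gender ~ Bernoulli(0.41), education with three
levels; time-varying smoking (binary) and body-mass category (three
levels) with strong persistence and exposure feedback (prior exposure
raises next-wave smoking and body-mass logits by 0.8 / 0.3–0.4);
three-wave binary exposure with serial dependence (prevalence rising
from ≈ 0.34 to ≈ 0.43); outcome on a blood-pressure-like scale
(residual SD 10 mm Hg) with direct exposure effects 0.5 / 0.8 / 1.0
mm Hg per wave, so true cumulative effects are of order 1–3 mm Hg
(chronic ≈ 3 with the feedback contribution). Coefficients were chosen
once to give moderate confounding and clinically plausible effect
sizes; they deliberately do not target any real cohort's marginals.
Variants: `null_design` (all exposure effects removed),
`additive_design(theta)` (no feedback, exact closed-form truth 1.5θ /
1.5θ / 1.5θ / 3θ for the four categories), and `nonlinear_design` (age
threshold and exposure-by-smoking interactions) for stressing the
random-forest algorithm.

What the fixture does *not* emulate: real covariate marginals or
dependence strengths, missingness, dropout, measurement error, and
informative sampling. Passing tests therefore demonstrate the
*machinery* (correct algorithms, calibrated uncertainty under a known
mechanism), not performance on any particular real cohort.

## Problem sizes used in the test suite

The end-to-end study runs J = 500 replicates of size m = 500 from the
n = 1576 fixture (bias checks use the first 200 replicates; coverage
uses all 500), with 50-resample bootstraps for g-computation and TMLE
and a 60-pass counterfactual truth; the acceptance script uses J = 200
and a 40-pass truth. These sizes keep Monte Carlo SEs of bias below
≈ 0.13 mm Hg and of coverage below ≈ 0.011 while keeping the whole
suite in the minutes range on a single core.

## Known limitations

* Continuous and count covariates other than gaussian are out of scope
  (no Poisson or time-to-event targets).
* The TMLE has no Super Learner layer and no cross-fitting; working
  models are GLMs.
* The cumulative-category MSM is assumed correctly specified by the
  truth construction; when effects differ between regimes pooled into
  one category, IPTW converges to a frequency-weighted within-category
  mean and can differ from the unweighted pooled truth by a small
  amount (well inside Monte Carlo error under the default fixture).
* Missing data, censoring and IPCW are unsupported by design.
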