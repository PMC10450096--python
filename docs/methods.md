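# Methods

This note documents the models, the defaults and why they were chosen, the
synthetic data-generating process and what it does and does not emulate,
and the numerical choices that affect results.

## Measurement model and scoring

Momentary states live on a z-standardized latent metric (mean 0, SD 1 in
the norming population).  Items follow the graded response model; each item
carries a discrimination `a > 0` and `K − 1` strictly increasing thresholds.
Response categories are 1-based everywhere (files, APIs), matching the
5-point numeric rating scales typical of momentary fatigue items.

Scoring is maximum a posteriori under a normal prior, N(0, 1) by default,
for every condition and every interim estimate.  The standard error of
measurement is defined as `(1/sd_prior² + Σ_j I_j(θ̂))^(-1/2)` — prior
precision plus summed item Fisher information at the mode.  This is the
standard adaptive-testing convention; it guarantees that the SE never
increases as items accumulate, the property the stopping rules lean on.
With no responses the estimate is the prior itself, so `se = 1` exactly.

Numerics: the posterior mode is found on the bracket [−6, 6] (the latent
metric is z-scaled; nothing lives beyond ±6) by a safeguarded Newton
iteration — the posterior is strictly log-concave, and a per-row gradient
sign bracket with bisection fallback protects against the oscillation that
raw Newton exhibits far from the mode; convergence is to steps below 1e−9,
well inside the 1e−6 contract, and the vectorized implementation solves
many hypothetical-response problems in one pass.  Survivor-curve
differences are computed in whichever tail is numerically stable
(`logistic(z)` vs `logistic(−z)`) so category probabilities never cancel
to zero; probabilities are floored at 1e−300 inside logs.

## Item selection and stopping

* `random` — uniform over unadministered items (the nonadaptive reference).
* `max_info` — argmax of item information at the current selection state.
* `mei` — maximum expected information: for each candidate, the predictive
  probability of each answer (evaluated at the current MAP point estimate,
  not integrated over the posterior — the simplest faithful reading of the
  criterion, documented here for reproducibility) times the candidate's
  information at the MAP recomputed with that hypothetical answer.

Ties in any argmax are broken uniformly at random with the session's seeded
generator.  Initialization (`init_theta`) affects only the *selection*
state for the first item — the scoring prior stays N(0, 1) — so prior
information chooses a good opening question without biasing the score.

Stopping rules: `fixed_length` (exactly n items), `se_threshold` (stop when
SE falls below a bound; SE < 0.3 corresponds to reliability 1 − SE² = 0.91),
and `classification_confidence` (stop when the symmetric Wald interval
`θ̂ ± z_{(1+c)/2}·SE`, default c = 0.95, excludes the cutoff).  A 5-item cap
always applies, and at the cap the decision is forced at the point estimate
(every prompt must yield a decision for sensitivity/specificity to be
defined on all prompts).  Asymmetric error costs could be expressed through
one-sided levels; the default is symmetric.  "Above" is strict:
`θ̂ > cutoff`; a value exactly at the cutoff is below.

## Cutoffs

Uniform cutoffs apply one z-value (default 1.0, ≈ the 85th percentile of a
standard-normal state distribution) to every prompt.  Dynamic cutoffs fit
the cosinor regression

    theta_i = b0 + b1 sin(2π hour_i / 24) + b2 cos(2π hour_i / 24) + r_i

by ordinary least squares to *all* of the person's previously observed
scores — run-in and night-time prompts included, since they exist precisely
to feed this fit — and set the cutoff to the predicted level at the current
hour plus `delta_sd` (default 0.5, a common minimally-important-difference
benchmark) residual SDs.  The residual SD uses the model-degrees-of-freedom
denominator n − 3.  The fit is recomputed at every prompt from scratch, as
the decision rule states.  With fewer than 3 usable points or a
rank-deficient design (e.g., two distinct hours), the fallback is
`mean(history) + delta_sd · SD(history)`.

Gating: classification decisions are made only after a `run_in_days`
(default 2) run-in and within the daytime window, which is half-open
[6, 18) — the boundary convention is fixed and tested since "between 6 AM
and 6 PM" does not define one.  During non-classifiable prompts the
variable/adaptive conditions switch to the SE < 0.3 stopping rule, so those
prompts still yield well-measured scores for cutoff estimation.  Cycles are
assumed stationary within a study; a trend hook would be the natural
extension but is deliberately not included.

## Synthetic data-generating process

The simulator replaces a real patient sample with a generative model whose
truth is known:

* person cycles: `beta0 ~ N(0, 0.7)`, amplitude `√(b1² + b2²) ~ U(0, 0.8)`
  with uniform phase, within-person residual SD `~ U(0.3, 0.9)`, and
  day-to-day cycle wobble SD `~ U(0, 0.4)` applied as fresh Normal
  perturbations of (b1, b2) each day;
* these defaults calibrate the pooled marginal variance of true states to
  ≈ 1 (0.49 + 0.11 + 0.39 + 0.05), keeping the z metric honest, which the
  tests verify empirically;
* schedules: 28 days × 5–6 prompts/day stratified over a 6:00–22:00 waking
  window with jitter, thinned completely at random to 91% compliance
  (missing-not-at-random compliance is out of scope);
* true dynamic cutoffs use the person-level generating cycle plus
  0.5 × within-person SD — the correct analogue of an estimated cutoff when
  the truth is known by construction; true classes are strict comparisons
  of true state vs true cutoff.

Responses are drawn from the GRM at the true state through one uniform
variate per (prompt, item), so any two conditions administering the same
item at the same prompt observe the same answer; this shared-truth,
shared-response design sharpens between-condition comparisons and makes
entire studies reproducible from one master seed (stage-named child seeds
for bank, population, schedule, truth, responses, sessions).

What this emulates well: person heterogeneity in level and rhythm, diurnal
structure, measurement error, compliance thinning.  What it does not:
response styles and careless responding, item-parameter drift or
within-person DIF, informative missingness, reactivity to repeated
assessment.  Passing tests therefore demonstrate the *measurement
machinery* under a clean generative model, not performance on any
particular clinical population; the synthetic default bank (13 items, 5
categories, discriminations in [1.5, 3.5], threshold centers in [−1, 2] —
fatigue banks are calibrated to be most informative above average severity)
is less informative than a real, professionally calibrated fatigue bank,
so absolute accuracy and item counts shift accordingly while the ordering
of methods is preserved.

## Evaluation

Sensitivity (specificity) is the median-person true-positive (negative)
rate: a logit-normal random-intercept model is fitted by maximum likelihood
with a fixed 21-node Gauss–Hermite rule to the correct/incorrect indicators
of truly-above (truly-below) prompts, and the intercept is back-transformed.
Degenerate all-correct data get an Agresti-style half-count continuity
correction and a boundary flag, so a perfect observer reports rates just
under 1 rather than an infinite logit.  Kappa comes from the
sensitivity/specificity/prevalence identity, with prevalence the empirical
truly-above rate among classifiable prompts.  Items-per-prompt variance is
decomposed between/within persons by unbalanced one-way method-of-moments
ANOVA.  Uncertainty and between-condition contrasts use a seeded cluster
bootstrap resampling persons (1000 draws by default), which replaces
Bayesian multivariate multilevel modeling with a self-contained estimator
of the same contrasts.

## Problem sizes used in checks

The packaged acceptance run uses the full reference design (106 persons ×
28 days, ≈ 14,900 prompts per condition).  Replicate-seed checks of the
method orderings use 20 seeds of a 30-person × 14-day study, and
cutoff-error checks use single-person histories over 28 days at three
wobble levels — sizes chosen so the whole suite runs comfortably on one
CPU while leaving the qualitative contrasts well resolved.

## Known limitations

* MEI evaluates predictive probabilities at a point estimate; fully
  Bayesian expected information would integrate over the posterior.
* The Wald stopping interval is symmetric and normal-theory; small-sample
  posterior asymmetry is ignored.
* Only MCAR compliance; no exposure control, content balancing, or
  multidimensional selection.
* The random-intercept likelihood uses fixed (non-adaptive) quadrature;
  with very large clusters the 21-node rule carries truncation error of
  order 1e−5 in cluster log-likelihoods (negligible for the estimates, and
  checked against dense integration in the tests).
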