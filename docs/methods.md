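# Methods

## Generative model

A size response is modelled in two independent stages. The visual stage
produces an unbiased estimate of the object size *s* with noise obeying
Weber's law, ŝ ~ N(s, (W_V·s)²); the motor stage maps the estimate
linearly into the response and adds implementation noise,
GA\* ~ N(k·ŝ + overshoot, σ²). Both noise sources are Gaussian and
independent, so the marginal response distribution is Gaussian with mean
k·s + overshoot and SD √((k·W_V·s)² + σ²). Assumptions worth making
explicit:

- **Linearity of the mapping.** The generator never produces convex or
  concave mappings; nonlinearity is only *measured* (see the convexity
  index below).
- **No response truncation.** Responses are not clipped at zero or at a
  biomechanical ceiling (maximum finger span). For the parameter ranges of
  interest (responses of 20–60 mm, SDs of 2–7 mm) truncation would be a
  ≥5σ event, but the model is not valid near such boundaries.
- **Unbiased visual stage.** Any constant response bias is absorbed into
  the overshoot.

All randomness flows from one `numpy.random.Generator` passed down the
call chain; identical seeds give bit-identical trial tables, and the CSV
writer/reader round-trips float64 exactly (`repr` on write,
`float_precision="round_trip"` on read).

## Default parameters

| parameter | grasping (MGA) | estimation (MSE) | units |
|---|---|---|---|
| mapping slope k | 0.7 | 1.0 | — |
| overshoot | 18 | 4 | mm |
| implementation noise σ | 6 | 2 | mm |
| visual Weber fraction W_V | 0.06 | 0.06 | — |

Object sizes default to {21, 28, 35, 42} mm, with 20 repetitions per size
and 20 subjects per cohort — the condition under which the
grasping/estimation dissociation is demonstrated. Under these values the
asymptotic apparent Weber fraction (OLS slope of the closed-form SD over
the four sizes) is 0.041 for estimation and 0.009 for grasping.

## Synthetic cohorts

`generate_experiment` draws, per subject and condition, an additive
Gaussian offset on the overshoot (SD `between_subject_sd`, default 0) and
optionally a multiplicative jitter on k (default off). Heterogeneity is
additive on the intercept because that is the structure the
random-intercept analysis models assume; the demonstration cohort uses
`between_subject_sd = 0` so that across-subject spread in the recovered
measures reflects sampling noise alone. Trial order within a block is
repetition-major with sizes interleaved; analyses pool over order, so the
order convention only matters to the drift component.

What the generator deliberately does **not** emulate: reach trajectories
and their kinematic landmarks' extraction, movement timing, missed or
repeated trials, tracking dropouts, block-order (Latin square) effects,
and any dependence of noise on fatigue or practice. Tests passing on these
tables therefore validate the estimation and inference machinery under
the stated model, not the model's fidelity to any particular empirical
data set.

### Drift (optional, disabled by default)

`DriftSpec` is a package convenience for exploring adaptation-like
dynamics, not an empirically fitted learning model. Within each
subject × condition sequence, every generative parameter interpolates
exponentially from its initial to its target value,
param_t = target + (initial − target)(1 − rate)^t, so `rate = 0` is a
no-op and `rate = 1` jumps to the target after the first trial.
Conditions listed as washout start fully adapted and relax toward
initial + retention·(target − initial): `retention = 0` is complete
washout, `retention = 1` complete persistence.

## Estimation pipeline

- **Trial exclusion**: within each subject × condition × size cell, trials
  with |response − cell mean| ≥ 2.5 × cell SD (sample SD, n−1) are
  removed. The cell, rather than the whole subject pool, is the unit so
  that large objects are not systematically flagged. Cells with n < 3 or
  zero SD pass through untouched and are flagged in the report.
- **Initial-repetition removal** (optional): repetitions 1..n within each
  subject × block × size, for designs where a feedback regime changes at
  block boundaries.
- **Summaries**: sample mean and SD per cell; SD undefined (and flagged)
  for singleton cells.
- **Slope measures**: per subject × condition, OLS of cell means on size
  (response slope k and intercept) and of cell SDs on size (apparent Weber
  fraction W and SD intercept). Plain OLS, not robust regression: only
  four size levels, and the measures feed subject-level tests that are
  themselves robust to per-subject estimation error.
- **Subject exclusion**: one pass, never iterated. A subject is removed if
  any of its cell means or SDs deviates ≥ 2.5 across-subject SD from the
  across-subject mean of that cell; zero-variance cells are skipped.
- **Implementation-noise recovery**: given the fitted slope k̂ and a known
  W_V, σ̂ averages √(max(0, SD_s² − (k̂·W_V·s)²)) over sizes. Negative
  residual variances (pure sampling noise) are clipped at zero.

## Inference

- **Paired contrasts**: classical paired t with Cohen's d =
  mean(diff)/SD(diff). Two identical vectors give a zero contrast; a
  constant non-zero shift (zero difference variance) raises a degenerate
  error rather than returning an infinite d.
- **Group contrasts**: Welch t; Cohen's d with the pooled SD.
- **Condition ANOVA**: statsmodels `MixedLM` with a by-subject random
  intercept, fitted by REML; the condition main effect is a Wald χ² on
  the joint fixed-effect coefficients (reference level = first condition
  in sorted order). η² is the sum of squares of the fixed-effect
  predictions about the grand mean over the total sum of squares —
  documented because η² definitions vary across packages. Subjects with
  missing cells are dropped listwise with a recorded warning. In a
  balanced two-condition design the Wald χ² equals the paired-t t²
  (verified to ~1e-3 relative; the residual difference is REML optimizer
  tolerance, not model disagreement).
- **JZS Bayes factor**: one-sample test of mean ≠ null against a point
  null, with a Cauchy(0, rscale) prior on the standardized effect size δ.
  BF₁₀ = ∫ f_t(t; ν, δ√n) Cauchy(δ; 0, r) dδ / f_t(t; ν, 0). The
  substitution δ = r·tan θ maps ℝ to (−π/2, π/2) and turns the prior
  weight into the constant 1/π, leaving a smooth bounded integrand for
  adaptive quadrature (scipy `quad`, marginal likelihoods resolved to
  1e-8 absolute; non-convergence raises rather than returning a value).
  Default rscale is √2/2 ≈ 0.707; any positive scale, including 0.717,
  is selectable. The test suite checks the implementation against an
  independent quadrature over the g-mixture representation of the same
  integral (and against pingouin) to 1e-6 relative error.
- **Adherence decision**: BF₁₀ ≥ 3 → Weber scaling *present*, ≤ 1/3 →
  *absent*, otherwise *anecdotal*. Cutoffs are arguments.
- **Convexity index**: the quadratic coefficient of an OLS fit of cell
  means on size (needs ≥ 3 distinct sizes); its sign labels the mapping
  convex/linear/concave with a configurable tolerance around zero
  (default 1e-8, appropriate for exact fixtures; simulation studies
  should widen it to their Monte-Carlo resolution).

Tests are two-sided throughout and no multiple-testing correction is
applied; reports list every test performed so readers can apply their own.

## Problem sizes and numerical choices

Parameter-recovery checks use 10⁵ trials per size, which puts Monte-Carlo
error an order of magnitude below the assertion tolerances (e.g. slope SE
≈ 6e-4 against a ±0.01 band). The dissociation study uses 100 replicate
cohorts of 20 subjects × 20 repetitions; the mixed-model type-I-error
calibration uses 1000 null simulations of 20 subjects × 2 conditions,
where the nominal Wald-χ² rejection rate at α = 0.05 is expected slightly
above 0.05 (~0.065) because the χ² reference ignores the t(19) tails.
Seeds for multi-replicate runs are derived with `numpy.random.SeedSequence.spawn`,
so replicates are independent streams and the whole study is reproducible
from a single integer.

## Known limitations

- The Gaussian/independence assumptions are untested conveniences of the
  model, not established facts about motor noise.
- The mixed model covers the balanced random-intercept case only; no
  Satterthwaite degrees of freedom, random slopes, or crossed designs.
- The drift component is qualitative plumbing; its rate/retention
  parameters have no empirical calibration.
- The exclusion rules operate per cell; data collected under protocols
  that pooled across sizes for outlier screening will differ slightly.
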