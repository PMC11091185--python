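# Methods

## The measurement problem

Cross-country comparisons built on Likert-type rating scales assume that
respondents everywhere map the same latent level onto the same response
category. When countries differ in *scale usage* — most prominently in
extreme response style (ERS), a content-independent preference for the
outermost categories — observed country means confound the target trait
with the style, and country-level correlations with external covariates can
be artifacts. This package implements the machinery to probe that
sensitivity: a multigroup Partial Credit Model (PCM), an ERS-extended
variant, a Bayesian latent regression of country trait means on a
standardized covariate, and a synthetic-data generator that reproduces the
confounding mechanism with known ground truth.

## Models

**Plain multigroup PCM.** Person p in country g answers item i on a
K-point scale (categories 1..K). With person trait θ_p and item thresholds
τ_i = (τ_{i,1}, …, τ_{i,K−1}),

    P(Y_pi = k) ∝ exp( (k−1) θ_p − Σ_{j<k} τ_{i,j} ).

Thresholds are shared across countries — the measurement-invariance
assumption the extended model relaxes. Thresholds may be disordered; no
reordering is applied.

**ERS-extended multigroup PCM.** A second person trait η_p (ERS) enters
through category scoring weights s_k:

    P(Y_pi = k) ∝ exp( (k−1) θ_p + s_k η_p − Σ_{j<k} τ_{i,j} ).

The default weights are the distance from the scale midpoint,
s_k = |k − (K+1)/2| (for K = 9: 4,3,2,1,0,1,2,3,4). With these weights the
model is *algebraically identical* to a plain PCM whose thresholds are
shifted person-specifically by τ′_{i,j} = τ_{i,j} + d_j η_p with
d_j = s_j − s_{j+1} ∈ {+1, −1}: positive η widens the outer categories'
intervals symmetrically (extreme preference), negative η widens the middle.
This equivalence is property-tested to machine precision and is the reason
the graded weights are the default; a binary extreme-vs-rest weighting is
available as a configuration alternative. On a two-category scale every
admissible symmetric weight vector is constant, so the ERS dimension is
unidentified and requesting the extended model raises an error.

**Latent regression.** Country trait means follow a quadratic function of a
standardized country covariate x_g (e.g. HDI):

    θ_p ~ N(μ_θ,g, 1),   μ_θ,g = β0 + β1 x_g + β2 x_g² + u_g,   u_g ~ N(0, σ_u²),
    η_p ~ N(μ_η,g, σ_η²),   μ_η,g ~ N(0, σ_μη²) subject to Σ_g μ_η,g = 0.

The regression is estimated *jointly* with the measurement model (one
stage), so the credibility intervals for β propagate measurement
uncertainty; a two-step fit-then-regress alternative would understate it.

**Identification.** σ_θ = 1 fixes the latent scale symmetrically across
countries (no reference country); the grand sum of all item thresholds is
zero (fixes the latent origin against β0); the country ERS means sum to
zero (fixes the ERS origin against the thresholds, via the d_j shift
direction). All three constraints hold exactly in every stored posterior
draw and are asserted on every accepted fit.

**Priors** (weakly informative): τ ~ N(0, 3²), β ~ N(0, 5²), half-Normal(2.5)
on σ_u, σ_η and the ERS-mean hyper-SD σ_μη. The country ERS-mean density is
evaluated in restricted form on the sum-zero subspace (G−1 effective
dimensions).

## Sampler

A seeded Metropolis-within-Gibbs scheme (no external PPL dependency):

- θ_p and η_p: vectorized single-site random-walk Metropolis over all
  persons at once, proposal scales adapted toward ≈0.44 acceptance during
  warmup and frozen afterwards; likelihood kernels are numba-compiled.
- μ_θ,g and β: exact conjugate Gibbs (normal means / Bayesian linear
  regression given μ_θ).
- μ_η: exact Gibbs draw of the Gaussian full conditional *conditioned on the
  sum-zero constraint* (sample the unconstrained conditional, then apply the
  closed-form Gaussian projection — this is the exact restricted
  conditional, not an approximation).
- σ_u, σ_η, σ_μη: univariate slice sampling on the log scale.
- τ_i: per-item blocked random-walk Metropolis (adapted toward ≈0.3
  acceptance).
- Two likelihood-invariant "shift" moves traverse the weakly identified
  ridges, accepted on prior ratios alone: a location move
  (β0, μ_θ, θ, τ) += c, and an ERS move (η += c, τ_{i,j} −= d_j c).
- A country-level *trade-off ridge move* for the extended variant: the
  quadratic (and linear) covariate contrast of the country ERS means is
  nearly exchangeable with the same contrast of the trait means — exactly
  the direction the confound scenario lives on — and mixes very slowly
  through person-level updates alone. The move proposes
  η_p += c_g, μ_η,g += c_g along a fixed mean-zero covariate contrast
  (preserving the sum-zero constraint) together with the Fisher-
  compensating trait shift θ_p += a_g c_g, μ_θ,g += a_g c_g, where
  a_g = −I_θη/I_θθ is the per-country information trade-off slope. Slopes
  and step sizes are adapted during warmup and frozen afterwards, so the
  proposal stays symmetric and the chain exact; an occasional 4× step
  helps traverse the full ridge.

During sampling the overall threshold location is identified only softly by
the priors; at storage time each draw is projected exactly onto the
grand-sum-zero constraint along the likelihood-invariance direction
(τ → τ − c, β0 → β0 − c, μ_θ → μ_θ − c, c the grand threshold mean). The
likelihood value is untouched by the projection; the only quantity whose
posterior is (negligibly, at these data sizes) affected by soft-vs-hard
prior handling is β0, and the grid-agreement check below bounds that effect.

**Defaults:** 4 chains, 1000 warmup + 1000 retained iterations, all streams
derived from one root seed (identical seeds give byte-identical draws). The
canned simulation studies use 2 chains with iteration counts chosen so the
convergence gates still pass on their designs (see below).

**Diagnostics.** Split-chain R-hat (own implementation, cross-checked
against arviz in the tests) and arviz bulk ESS. A fit is flagged
`converged_ = False` — never silently accepted — when any key parameter
(β, σ_u) has split R-hat ≥ 1.01 or when bulk ESS for β1 or β2 is ≤ 400.
The variant comparison refuses non-converged inputs. Equal-tailed posterior
intervals use linear-interpolation percentiles (numpy's default).

**Standardized coefficients.** Per draw, β1* = β1·SD(x)/SD(μ_θ) and
β2* = β2·SD(x²)/SD(μ_θ), with SDs over the G countries (ddof = 1); the
reported value is the posterior mean. Standardizing by the SD of the
model-implied country means (rather than person-level θ) makes β* a
country-level effect size; this convention is one of two defensible
choices and is documented rather than claimed unique.

## Synthetic data

The generator mirrors the hierarchical model exactly (its closure is
tested: the emitted ground truth recomputes every cell probability).
Defaults emulate a 45-country, nine-point-scale survey; per-country sample
size (100) and item count (6) are moderate survey-scale choices since no
canonical values exist for them, and β0 = 1 places the trait mean above the
scale midpoint — deliberate, because the ERS confound only biases observed
means when the trait distribution is off-center. Within-country SDs are
homogeneous by default. Item thresholds are drawn N(0,1) and centered to
grand-sum zero to match the estimation constraint; the covariate is drawn
standard-normal and standardized exactly (sample SD, denominator G−1).

**Scenario presets.** Cases A/B/C reproduce the three-country scale-usage
illustration: baseline (μ_η = 0), middle-preference (μ_η = −1),
extreme-preference (μ_η = +1). The **confound scenario** sets
β1 = β2 = 0 and μ_η,g = γ2 (x_g² − mean(x²)): the style gradient, not the
trait, carries the quadratic covariate signal. γ2 = −0.5 spans roughly two
within-country SDs of η across countries — a strong but not extreme style
gradient; the negative sign mirrors the inverted-U pattern the method is
designed to interrogate.

What the generator does *not* emulate: item-level DIF, non-normal trait
distributions, acquiescence or midpoint styles, planned missingness, and
real surveys' unbalanced country sizes. Passing recovery tests therefore
show the estimator is consistent with its own generative assumptions, not
that those assumptions hold in any particular survey.

## Validation studies (`erspcm.experiments`)

Problem sizes are frozen in the module so every result is reproducible from
one seed:

- **Equivalence**: max |p_weight − p_shift| over 1000 random draws of
  (K, θ, η, τ); must be < 1e−12.
- **Recovery**: G = 30 countries × 200 persons, 8 items, K = 9, true
  β2 = −0.3 with modest ERS heterogeneity (μ_η,g ~ N(0, 0.3²), centered);
  10 replications, extended-model fit (2 chains, 500 + 1000 iterations).
  A replication whose fit trips the convergence gate is rerun once with
  2 × (1000 + 4800) iterations — triggered by the flag, never silently,
  with at most two reruns per study to bound the total runtime.
  Checks: 95% CI covers the truth in ≥ 8/10 replications, |mean bias| < 0.1,
  convergence gates pass on the final fits.
- **Spurious effect**: confound scenario at G = 30 × 100 persons, 6 items,
  γ2 = −0.5; both variants fit (2 chains, 500 + 2500). Checks: unadjusted
  |β2| exceeds adjusted, and the adjusted 95% CI contains 0.
- **Grid agreement**: a two-country, 30-persons-each, 2-item, K = 3 problem
  with thresholds and σ_u clamped at truth and the linear-only regression
  (x² is collinear with the intercept at G = 2). The MCMC posterior mean of
  β0 must sit within 0.05 of a dense-grid reference that integrates person
  traits by 31-node Gauss–Hermite quadrature, country residuals by a second
  quadrature layer, and (β0, β1) over an 81×81 grid with identical priors —
  an algorithmically independent route to the same posterior.

## Numerical choices and edge cases

- All category probabilities are computed in log space with
  max-subtraction; they stay finite and normalized for |θ|, |η|, |τ| up to
  at least 30.
- Missing responses (coded 0) contribute zero to the likelihood
  (ignorable missingness).
- Split R-hat of a constant chain is defined as 1.0 (guarded against
  floating-point summation noise); a single chain is an error.
- Degenerate slice-sampling slices fall back to the current value rather
  than looping.
- Draws serialize to CSV (one row per chain × iteration, one column per
  scalar) with a JSON sidecar for metadata and diagnostics; reports are
  reproducible from the draws file alone.

## Known limitations

- The sampler is random-walk based for person traits and thresholds;
  gradient-based samplers would scale better to much longer surveys.
- Only extreme response style is modeled; acquiescence, midpoint styles,
  mixture or IRTree-type decompositions are out of scope.
- The latent regression assumes normal country residuals and a quadratic
  form; model comparison across functional forms is not provided.
- Refitting the original 45-country study requires its public deposit
  (not redistributed here) and substantially longer chains than the canned
  studies use.
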