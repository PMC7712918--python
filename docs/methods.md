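# Methods

## Models

**Hunting-area model.** Reported team areas are treated as log-normal
within each HMP: A ~ Log-Normal(log m_kl, s_l).  The location is built
from nested effects, log m_kl = W + L_l + C_kl with L_l ~ Normal(0, T)
and C_kl ~ Normal(0, t); the log-scale spread is county-specific,
s_l = exp(u + v_l) with v_l ~ Normal(0, z).  Scale parameters (T, t, z)
carry Log-Normal priors, locations (W, u) Normal priors.  Because the
model lives on the log scale, s_l is a scale-free measure of within-HMP
dispersion of team areas.

**Harvest models.** A team's seasonal harvest count K with exposure A
(ha) follows a Poisson process whose rate may vary across teams.  Six
nested variants arise from three switches:

- within-HMP variability (α): team rates are Gamma distributed around
  the HMP mean, giving a Gamma–Poisson (negative binomial) count model
  with mean μ_kl·A·δ and shape α_kl; without the switch the count is
  Poisson (the α→∞ limit);
- rate–variability association (γ): log α_kl = υ + γ(χ_kl + λ_l), so
  HMPs with above-average log rate are systematically more (γ<0) or less
  (γ>0) variable; otherwise log α_kl = υ;
- relative-area effect (φ): δ = (A/m̄_kl)^φ multiplies the per-area
  rate, with m̄_kl the typical team area of the HMP (posterior median of
  m_kl).  φ=0 means no effect; φ<0 means bigger areas harvest less per
  hectare; φ=−1 makes a team's expected harvest independent of its area.

The rate hierarchy mirrors the area model: log μ_kl = ω + λ_l + χ_kl,
λ_l ~ Normal(0, τ), χ_kl ~ Normal(0, σ).  The negative-binomial pmf is
used in its mean/shape parameterization,
log P(K) = lgamma(K+α) − lgamma(α) − lgamma(K+1) + α log(α/(α+m)) +
K log(m/(α+m)) with m = μAδ.

m̄_kl is computed once from the pooled (all chains) area posterior and
shared by every harvest model, so the area model never needs refitting
per species or per model variant.

## Priors

Priors are elicited from 95% plausibility ranges by the two-standard-
deviation rule: location = midpoint, scale = (hi−lo)/4, applied on the
log scale for positive parameters (`priors.elicit_from_range`).  The
default configuration (`priors.default_priors`) is, as (location,
scale):

| parameter | prior | default | elicited from |
|---|---|---|---|
| W | Normal | (5.8, 1.7) | typical team area 10–10,000 ha |
| T | Log-Normal | (−0.38, 0.61) | county factor 1.5–100 at 2 SD |
| t | Log-Normal | (−1.3, 0.86) | HMP factor 1.1–20 at 2 SD |
| u | Normal | (−0.77, 0.36) | within-HMP area CV 0.1–10 |
| z | Log-Normal | (−1.5, 0.80) | spread factor 1.1–10 |
| ω | Normal | (−8.7, 4.3) | 1 animal nationally … 1 per ha |
| τ | Log-Normal | (−0.38, 0.61) | as T |
| σ | Log-Normal | (−1.3, 0.86) | as t |
| υ | Normal | (0, 3.0) | rate CV 1/20–20, α = 1/c² |
| γ | Normal | (0, 1.0) | CV at most doubles per rate doubling |
| φ | Normal | (0, 0.50) | between no effect and quadratic growth |

Two defaults are deliberately kept at their printed reference values
even though re-deriving them from the stated ranges gives something
else: the u scale (derivation ≈ 0.77, default 0.36) and the z location
(derivation ≈ −0.76, default −1.5).  The derivations are exposed and
tested; the defaults reproduce the reference analysis.  All priors are
overridable from a YAML file (`name: [location, scale]`).

## Sampling

No general-purpose gradient-based PPL is part of this package's
dependency footprint, so `huntstat.mcmc` implements the sampler
directly: leapfrog HMC with a Metropolis accept step, jittered
trajectory length (uniform 1..32 steps), dual-averaging step-size
adaptation, and a diagonal mass matrix estimated in doubling warmup
windows (Stan-style shrinkage toward a unit metric).  The Metropolis
correction keeps the chain exact for the target regardless of tuning;
adaptation affects only efficiency.  Gradients are analytic and
vectorized per model and are verified against finite differences in the
test suite; the sampler itself is verified against Gaussian targets and
a conjugate Gamma–Poisson posterior.

Both models are sampled on an unconstrained vector: positive parameters
on the log scale (their Log-Normal priors become Normal there, absorbing
the Jacobian) and random effects non-centered (λ = τλ*, χ = σχ*, with
standard-normal primitives), which removes the funnel geometry that
otherwise stalls HMC in hierarchies.

Default settings mirror the reference analysis: 4 chains × 30,000
iterations with 5,000 warmup.  "80% thinning" is read as keeping every
fifth post-warmup draw (20% kept); the alternative reading (dropping
every fifth) would barely reduce output size, which is the stated
purpose of thinning.  The dual-averaging target acceptance defaults to
0.9 rather than 0.99: 0.99 is a NUTS-specific remedy for divergent
transitions, while for fixed-length HMC with the Metropolis correction
0.9 is the efficient operating point; divergences are counted and
warned about separately (energy-error threshold 500).

Harvest chains are initialized over-dispersedly from the data: ω around
the mean of county log harvest/area ratios, λ_l and χ_kl around the
county/HMP log-ratio residuals, with a Normal(0, 0.5) fallback wherever
a ratio has zero numerator (zero-harvest HMPs, and — beyond the
reference recipe — zero-harvest counties, which train/validation splits
can create even after all-zero counties are excluded); υ, γ, φ from
standard normals and τ, σ from Gamma(5, 5).  The area model uses
data-centered jittered initialization.  Convergence warnings fire at
split-R̂ > 1.01 (area) and > 1.05 (harvest), and a large inter-chain
spread in mean log posterior flags a stuck chain for reseeding.

## Prediction

For each of Q predictive samples, one area-posterior draw and one
harvest-posterior draw are paired independently and uniformly with
replacement.  Team areas are drawn from Log-Normal(log m_kl, s_l) until
their running sum overshoots the unreported area U_kl; the overshooting
team's *area* is clipped so the areas sum to U_kl exactly, and its
harvest is sampled with the clipped exposure.  Clipping the exposure
(rather than discarding or keeping the overshoot) preserves
E[κ_kl] = μ_kl·U_kl exactly under the Poisson model — by Poisson
thinning the HMP total is then exactly Poisson(μU), which the tests
verify by a goodness-of-fit check.  Team harvests follow the fitted
variant: Poisson(μAδ), or Gamma(shape α, mean μAδ) team rates mixed
with Poisson.  Totals aggregate exactly draw by draw.

Summaries report the median and central credibility intervals of
reported-plus-predicted totals using the nearest-order-statistic
empirical quantile (`numpy` method `"nearest"`), which keeps interval
endpoints on attainable integer values.

## Validation

The train/validation workflow splits reports by random permutation into
deterministic halves (not i.i.d. assignment), refits on the training
half, and predicts the harvest on the area covered by the held-out
reports (the unreported area is overridden by the validation-covered
area per HMP).  The score is the posterior predictive mass at the
observed count.  When fewer than 10,000 samples (configurable) hit the
observed value, the empirical mass is replaced by jittered kernel
density estimation: uniform [−0.5, 0.5) jitter makes the integer samples
continuous, a 1-D Gaussian KDE (bandwidth: Scott's rule by default,
configurable) is fitted, and the density at the observed integer is
reported.  Jittering gives unbiased kernel estimates for discrete data;
the exact KDE variant (kernel, boundary handling) is a documented
configuration choice, not a fixed algorithm.

PSIS-LOO computes per-report leave-one-out predictive densities from
the in-sample pointwise log-likelihood matrix by Pareto-smoothed
importance sampling (smoothing delegated to `arviz.psislw`; reports
with zero-variance weights are exact and flagged k = −∞).  Reports with
Pareto k above 0.7 are refitted exactly (model refit without the
report; its predictive density averaged over refit draws).  ELPD
differences between models are reported with the standard error
√(n·var(pointwise differences)) and flagged at 2 and 4 SE.

## Synthetic data

The generator draws from the models' own generative structure, so
passing recovery tests demonstrates internal consistency — correct
likelihoods, sampler, and prediction — not robustness to real-data
features the models do not describe (reporting bias correlated with
harvest, spatial autocorrelation, year-to-year dynamics, area rounding
or misreporting).  A `reporting_bias` knob (default off) exists solely
to create violations of the reporting-independence assumption for
robustness experiments.

Defaults define the study conditions: 4 counties × 6 HMPs × 25 teams
with 30% reporting coverage; area truth W=7.0 (median team area ≈ 1,100
ha, matching the scale of national reporting data), T=0.83, t=0.42,
z=0.22 (the reference area-model posterior medians), u=−0.7; harvest
truth ω=−6.2 (≈0.002 animals/ha, a common-game magnitude), τ=0.5,
σ=0.4, υ=−0.5 (team rates more variable than exponential), γ=0.5,
φ=−0.3.  Huntable area per HMP is the sum of all generated team areas,
so the true unreported harvest is known exactly.

## Numerical choices

- Positive-parameter sampling on the log scale; no constrained
  transforms elsewhere.
- Non-finite log densities at extreme exploratory points are treated as
  rejected divergent transitions rather than errors.
- Identifiers are opaque strings; a dense integer index
  (`data_model.IndexedData`) backs all vectorized likelihoods.
- Reported area exceeding huntable area is a hard input error (it would
  make the unreported area negative); a relative tolerance of 1e-9
  absorbs rounding from full-coverage synthetic data.
- The conjugate Gamma posterior for a single-HMP Poisson model is used
  only as a test oracle (its prior shape/rate are chosen explicitly in
  the tests; vague conjugate priors are exactly what the hierarchy is
  there to replace).

## Problem sizes

Tests and examples run at desk scale by design: single chains of
700–2,500 iterations on scenarios of 4–6 counties with 10–40 teams per
HMP, 20 replicates for parameter-recovery checks and 10 for the
directional experiments, and 10³–10⁵ predictive samples depending on
the property checked.  Full-scale settings (4 × 30,000 iterations, 10⁶
predictive samples) remain the configured defaults.

## Limitations

- The sampler uses a diagonal metric and fixed-length jittered
  trajectories; strongly correlated posteriors sample less efficiently
  than under NUTS with a dense metric.
- No spatially structured effects (CAR/GP), no covariates beyond team
  area, no multi-year dynamics.
- The framework assumes reporting is independent of harvest; with
  voluntary reporting this is an assumption, not a guarantee, and
  nothing in the data can verify it.  Trend estimates are more robust
  than absolute levels if the bias is stable across years.
- Predicted non-reporting team counts are a by-product of the area
  sampling and are not calibrated against any team census.
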