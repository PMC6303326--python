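# Methods

This note documents the statistical procedures `forestbpr` implements, the
choices made where conventions were genuinely open, and what the synthetic
generator does and does not emulate.

## Data model and derived variables

A plot table has one row per forest plot: ecoregion label, MAT (°C), TAP
(mm), aridity index (mean annual precipitation over potential
evapotranspiration), soil C:N, stem density, stand age (yr), total
above-ground live biomass, and tree species richness (≥ 1 on a forested
plot; unforested rows are rejected at read time). Productivity is the mean
annual biomass increment, biomass / stand age — above-ground only, so all
conclusions concern above-ground productivity. Biomass units are carried as
metadata; every model works on log or standardized scales, so the analysis
is unit-covariant. Rows with a missing value in any required column are
excluded before analysis (complete-case), with per-column counts reported;
binning happens after this filter (configurable).

## Climate binning

MAT and TAP each get k = 10 quantile classes computed from the filtered
plot distribution, crossing to 100 climatic units. Quantiles use linear
interpolation between order statistics (R's default type 7), which is
deterministic and balances class counts to ±1 on tie-free data. Interval
convention (fixed because reproducibility demands one): classes are
half-open `[b_i, b_{i+1})`, the last interval closed, and a value exactly
on an interior breakpoint ascends to the upper class. Duplicate
breakpoints from heavy ties collapse (with a warning) to fewer effective
classes. Units are labelled by the aridity of their member plots —
mean by default, median available — against the standard thresholds:
[0.03, 0.2) arid, [0.2, 0.5) semi-arid, [0.5, 0.65) dry sub-humid,
≥ 0.65 humid.

## Bivariate BPR classification

Within each unit with ≥ 4 plots (configurable) and positive productivity
(zero-productivity rows are dropped with a count — the log is undefined),
two Gaussian GLMs of log productivity on richness are fitted: linear and
quadratic. Conventions match R's `glm`, verified against it to 8+ decimal
places: log-likelihood at the ML residual variance RSS/n, AIC counting the
error variance as a parameter (k = p + 1), coefficient SEs from the
dispersion RSS/(n − p). Tests are two-sided z-tests (the large-n
equivalent of t-tests; at the unit sizes involved the difference is in the
third decimal of the p-value). The lower-AIC model is selected, ties going
to the simpler linear model. Classification: a significant (p ≤ 0.05)
positive/negative linear slope in a selected linear model gives
`linear_positive`/`linear_negative`; a significant negative/positive
quadratic term in a selected quadratic model gives
`concave_negative`/`concave_positive`; anything else is
`non_significant`. Note one intrinsic property of this rule: under a true
linear BPR the quadratic model is AIC-selected with probability ≈ 0.16,
and about two thirds of those selections end `non_significant`, so even a
strongly linear unit is correctly labelled only ~89% of the time. No
multiple-testing correction is applied across units.

## Regime boundary

Units labelled `linear_positive` or `concave_negative` enter a binomial
logit of type on (mean MAT, mean TAP) — one observation per unit,
unweighted by default (weighting by plot count is an option; unit climate
means are used rather than class indices or midpoints). The boundary is
the line `intercept + c_MAT·MAT + c_TAP·TAP = 0`, i.e. P(concave) = ½.
With ~100 well-separated units the ML fit can diverge (complete
separation); this is detected (diverging coefficients or vanishing
residual deviance) and a small ridge-penalized fit (α = 1e−4) is
substituted and flagged, so a boundary is always reported. A vertical
boundary (c_TAP = 0) is reported as a constant-MAT line.

## Hierarchical Bayesian model

Within each unit with ≥ 30 complete-case plots (configurable), the system
of five sub-models listed in the README is assembled. Density, age, soil
C:N and productivity are log-transformed; every predictor role is
standardized by twice its sample SD (n−1 denominator), making effect sizes
comparable across binary-like and continuous predictors. Richness is
standardized first, then squared, keeping β₁₇ and β₁₈ interpretable at
the richness mean (standardizing the square instead is exposed as an
alternative). Each sub-model has its own ecoregion random intercept,
i.i.d. normal with its own SD; with a single ecoregion the random
intercept degenerates to the fixed intercept (warned).

Priors: N(0, variance 1000) on intercepts and slopes. The variance
components need priors too; half-normal(scale 1) on the random-intercept
and residual SDs is the package's choice — weakly informative and proper
on the standardized scale — and both scales are configurable.

### Sampling

The five sub-models share no parameters, so the joint posterior factorizes
and they are sampled independently (a subset fit is exact for its own
parameters). Sampling uses `emcee`'s ensemble MCMC with differential-
evolution and snooker moves; "chains" are independent seeded ensemble
runs (default three), with defaults of 100,000 iterations and 5,000
burn-in, and a `desk_profile` (3 × 2,000, 500 burn-in) for desk-scale
work. For sampling, the ecoregion intercepts are integrated out — exactly,
via the per-group compound-symmetry covariance for normal responses, and
by 31-node adaptive Gauss–Hermite quadrature for the Poisson sub-model
(each group's likelihood depends on its intercept only through Σy and
Σexp(η), so the one-dimensional integral is cheap; the quadrature agrees
with direct numerical integration to ~1e−12). This removes the
funnel geometry and leaves p + 2–3 dimensional, well-conditioned
posteriors. The un-marginalized joint density (explicit non-centered
random effects) remains the reference; tests verify it term by term
against an independent `scipy.stats` oracle to 1e−8.

Walkers initialize in a cloud around the least-squares / Poisson-GLM
solution, scaled to ~2 ML standard errors. Treating each walker in each
run as a chain, split-R̂ and effective sample size are computed per
monitored parameter (intercepts, slopes, SDs); a fit is flagged
non-converged when any R̂ > 1.05 or ESS < 100. Summaries are posterior
means, SDs, equal-tailed credible intervals (the highest-density variant
was not chosen because equal-tailed matches common Gibbs-sampler summary
conventions; the level is configurable) and P(β > 0) as the fraction of
positive draws. Seeds derive deterministically from a base seed and the
unit id, so reruns are identical.

### Posterior BPR classification

From the pooled draws of β₁₇ and β₁₈: `concave_negative` if
P(β₁₈ < 0) > 0.95; `concave_positive` if P(β₁₈ > 0) > 0.95;
`linear_positive` if P(β₁₇ > 0) > 0.95 and the β₁₈ CI overlaps zero;
`linear_negative` (an explicit extension — the classical rule set leaves
a significantly negative linear term with a null quadratic unlabelled)
symmetric to it; otherwise `non_significant`. The four rules are not
mutually exclusive as usually stated — a strong hump typically also has a
credibly positive linear term — so concavity takes precedence; the
precedence is configurable. At these draw counts P(β > 0) > 0.95 and a
95% equal-tailed CI excluding zero are near-equivalent; both quantities
are reported.

## Synthetic generator

The generator is the package's test bed: it produces tables with exactly
the statistical structure the model assumes, plus stored truth for
recovery tests.

* **Climate**: truncated bivariate normal in (MAT, TAP) with configurable
  location, spread and correlation (default ρ = 0.3). The continental
  preset spans MAT −3.8…23.9 °C and TAP 79…3375 mm with a deliberately
  dry-shifted, wide precipitation cloud (mean 900 mm, SD 700 mm) so that
  all four aridity classes — and ~23 dry units of the 100 — are populated.
* **Aridity index**: TAP / PET with the linear proxy
  PET(MAT) = 500 + 60·MAT mm — monotone in both arguments and positive
  over the supported range. Only the class labels matter downstream.
* **Ecoregions**: k-means clusters (default 194, the approximate number of
  US ecoregions) on standardized climate plus unit-SD "geography" jitter.
  The jitter matters: with pure climate clustering an ecoregion is a
  deterministic function of the climatic unit, each unit holds only a few
  ecoregions, and the realized random-intercept draws act as cluster
  noise that the unit-level bivariate GLM (which ignores ecoregions)
  mistakes for curvature. Loose alignment reproduces the premise that a
  climatic unit pools plots from many geographically distinct ecoregions.
* **Structure**: log density, log age and log C:N respond linearly to
  standardized climate with ecoregion intercepts (SD 0.2) and residual
  SDs 0.5 / 0.6 / 0.25; richness is Poisson with a log link on climate
  and stand structure, floored at one species; log productivity responds
  to all five predictors (residual SD 0.35) plus the planted richness
  effect; biomass is back-computed as productivity × age, making the
  productivity derivation an exact inverse. The default slope magnitudes
  (|β| = 0.1–0.5 on the 2-SD scale) give realistic richness ranges
  (~2–40 species) and productivity spreads.
* **Regimes**: the richness effect is planted on the 2-SD-standardized
  richness scale. Scenario presets: `null` (no structural effects at all
  and no shared spatial heterogeneity — a true null under which the
  bivariate classifier's false-positive rate is its nominal ~9%),
  `dry_positive` (β₁₇\* = 0.9), `mesic_hump` (β₁₈\* = −1.0), and
  `continental`, which blends the two logistically in the aridity index —
  centered at aridity 0.575 (mid dry-sub-humid), width 0.025, with
  weights snapped to exactly 0/1 beyond the 5%/95% points so that every
  arid and semi-arid plot has exactly β₁₈\* = 0 and every humid plot the
  full hump. The planted boundary is therefore the curve
  TAP = 0.575·PET(MAT). Effect magnitudes were chosen so the regimes are
  clearly expressed at ~200 plots per unit, mirroring a setting where the
  vast majority of units show significant BPRs.
* **Missingness**: completely-at-random per covariate cell (2% in the
  continental preset), written as `NA`.

What the generator does **not** emulate: spatial coordinates and spatial
autocorrelation beyond ecoregion membership, the irregular empirical shape
of the climate cloud, species identities or composition (richness is a
count), measurement error in biomass and age, and non-random missingness.
Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes — not that real inventory data satisfy those
assumptions.

## Problem sizes and numerical notes

Simulation-based checks run at desk scale by choice: regime recovery on
20,000 continental plots (100 units of ~180 complete cases), type-I
calibration on 100 null replicates of 12,000 plots in a 5 × 5 grid
(~480 plots per unit, where the z-test's small-sample inflation is
negligible), and hierarchical CI coverage on 25 replicates of 2,000 plots
with 10 ecoregions at the desk MCMC profile. Degenerate inputs are handled
rather than crashed on: perfect fits (zero RSS) select the linear model
and classify by sign; units below the size minimum are marked
non-estimable; quadratic designs with fewer than three distinct richness
values fall back to the linear model; empty tables are refused
explicitly.

## Known limitations

The Poisson sub-model ignores the floor-at-one in the generator (a ~0.1%
effect at default intensities). Ensemble MCMC at the desk profile yields
effective sample sizes in the thousands, adequate for 95% intervals but
not for extreme tail quantiles. The boundary logit treats unit labels as
data, ignoring their classification uncertainty. Random intercepts are
independent across sub-models; correlated ecoregion effects (e.g. a
shared productivity–richness ecoregion signal) are not modelled — under
such correlation the unit-level bivariate GLM picks up real confounded
association, which is a property of the marginal estimand, not a software
defect.
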