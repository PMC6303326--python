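# forestbpr

Climate-resolved analysis of the biodiversity–productivity relationship
(BPR) in natural forests, for ecologists working with large plot-level
forest-inventory tables (FIA-style: one row per plot with climate, soil,
stand structure, above-ground biomass and tree species richness).

Across a large climatic gradient the apparent BPR is not one curve: the
relationship between tree species richness *S* and stand productivity
(mean annual biomass increment, total above-ground biomass / stand age) is
linear-positive in dry climates and hump-shaped in mesic ones. `forestbpr`
implements the full analysis that resolves this:

1. **Climate binning** — plots are placed in a 10 × 10 grid of quantile
   classes of mean annual temperature (MAT) and total annual precipitation
   (TAP): 100 *climatic units*, each labelled arid / semi-arid /
   dry sub-humid / humid by its mean aridity index.
2. **Bivariate BPR per unit** — Gaussian GLMs of log productivity on *S*
   (linear) and on *S*, *S*² (quadratic); AIC selects the model and the
   z-test on the selected richness term labels the unit
   `linear_positive`, `linear_negative`, `concave_negative`,
   `concave_positive` or `non_significant`.
3. **Regime boundary** — a logistic regression of the two dominant labels
   on unit climate means gives the dividing line
   P(concave) = ½ in MAT–TAP space.
4. **Hierarchical Bayesian structural model** — within each unit, five
   sub-models with 18 slope coefficients β₁–β₁₈ and ecoregion random
   intercepts:

   * log stem density ~ MAT, TAP (β₁, β₂)
   * log stand age ~ MAT, TAP (β₃, β₄)
   * log soil C:N ~ MAT, TAP (β₅, β₆)
   * richness ~ Poisson(log link): MAT, TAP, density, age, C:N (β₇–β₁₁)
   * log productivity ~ MAT, TAP, density, age, C:N, *S*, *S*² (β₁₂–β₁₈)

   Every predictor is standardized by twice its sample SD; priors are
   N(0, variance 1000) on intercepts and slopes; sampling is MCMC with
   three seeded chains. The posterior of β₁₇ (linear richness term) and
   β₁₈ (quadratic) classifies each unit's BPR from credible intervals and
   tail probabilities.
5. **Synthetic data** — a first-class generator producing FIA-like tables
   with known structural truth (climate cloud, ecoregions, Poisson
   richness, planted BPR regimes), so every stage is testable end to end
   without access to inventory data.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/02_bivariate_bpr.py` (20,000 synthetic plots, continental
scenario, seed 42) prints:

```
BPR types over the 100 climatic units:
  concave_negative   74
  linear_positive    20
  non_significant    5
  concave_positive   1

dry units linear-positive: 74% of 23
humid units concave-negative (hump): 97% of 67

logistic regime boundary at mean MAT (10.4 degC): TAP = 577 mm
planted boundary (truth): TAP = 645 mm
```

Read: of the 100 climatic units, the humid ones are almost all hump-shaped
(a significant negative quadratic richness term — productivity rises then
falls with richness), the arid/semi-arid ones are predominantly
linear-positive, and the fitted logistic division between the two regimes
falls near the precipitation threshold the generator planted (the exact
percentages move a few points from seed to seed). The hierarchical model
(`examples/03_hierarchical_bpr.py`) recovers planted richness terms
β₁₇ = 0.3, β₁₈ = −0.05 with covering 95% credible intervals and classifies
the unit `concave_negative`.

A thin CLI mirrors the stages:

```bash
forestbpr simulate --scenario continental --n-plots 20000 --seed 42 \
    --out plots.tsv --truth truth.json
forestbpr bin --in plots.tsv --k 10 --out grid.json --units units.tsv
forestbpr bivariate --in plots.tsv --grid grid.json --out bpr_units.tsv
forestbpr boundary --units bpr_units.tsv --summaries units.tsv --out boundary.tsv
forestbpr run-all --scenario continental --seed 42 --out-dir out/
```

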