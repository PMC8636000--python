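# Methods

`florsel` implements the statistical chain used to quantify how herbivores
shape natural selection on floral traits across plant populations, in a
paired herbivore-exclusion design: each marked pair of plants contributes
one individual exposed to ambient herbivory (HP) and one from which
herbivores are manually removed (HE).

## Selection analysis within populations

For each population × treatment slice we compute relative fitness
`w_i = W_i / mean(W)` from total seeds per plant and standardize each of
the three floral traits (flowering start date in day-of-year, flower
number, corolla size in mm) to mean 0 and variance 1, using the n−1 sample
SD throughout. Directional selection gradients `β` are the coefficients of
the multiple OLS regression of `w` on the standardized traits; with the
optional squared terms, quadratic gradients use the doubling convention
`γ_ii = 2 × fitted coefficient`. Collinearity is screened by variance
inflation factors computed from intercept-adjusted auxiliary regressions
(`VIF_k = 1/(1 − R²_k)`); an informational note applies at VIF ≥ 1.8 and a
multicollinearity warning at VIF > 5, the regime in which quadratic terms
typically become unstable. Exact fits (zero residual SS) report their
coefficient p-values as undefined rather than zero.

Standardization and relativization are slice-wise (per population ×
treatment) by default. Because pooling treatments within a population is a
defensible alternative reading of "using the original data", both modes are
implemented (`reference=` / `pooled_standardization=`); the slice-wise mode
is the default and is what every downstream stage uses.

The opportunity for selection is `I = Var(w)` (sample variance, n−1). It is
treated as measured without sampling error because seed set is recorded for
every marked plant — a census, not a sample.

## Treatment contrast

Herbivore-mediated selection on a trait is the contrast
`Δβ_herb = β_HP − β_HE` with standard error `√(SE_HP² + SE_HE²)`. Its
per-population significance is taken from the trait × treatment term of a
per-population ANCOVA of `w` on traits, treatment, and trait × treatment
(slice-standardized inputs); a z-test of `Δβ/SE` is reported alongside, and
the two can disagree slightly — the ANCOVA term is authoritative.

## ANOVA / ANCOVA conventions

All factorial tables use sequential (Type I) sums of squares with terms
entering exactly in the order the model is written: main effects (traits,
population, treatment), then trait × population and trait × treatment, then
trait × population × treatment. Term order matters: if a trait's
interaction terms are tested before another trait's main effect has entered
(as happens when a formula engine regroups terms), the interaction F
statistics absorb unmodelled main-effect variation and become
anticonservative. Sequential SS are computed by incremental least squares
on term-wise design blocks (full dummy coding; degrees of freedom are rank
increments), which makes every F statistic identically the nested-model
formula `((RSS_reduced − RSS_full)/Δdf)/(RSS_full/df_resid)`. A marginal
(Type II) option is provided; for balanced designs the two coincide.

`log10` transforms of counts that can be zero (fruits, seeds) use
`log10(x + 1)`; herbivory intensity uses a square-root transform.

## Across-population meta-regression

Each population contributes one point: mean HP herbivory intensity `x`
(proportion of a plant's flowers damaged, averaged over HP plants;
untransformed) against either the opportunity for selection or the absolute
mediated gradient.

* **Opportunity for selection (models A/B):** ordinary least squares,
  linear vs quadratic, compared by `AIC = n·ln(RSS/n) + 2k` with `k`
  counting coefficients plus the error variance (the Gaussian constant is
  common to both candidates and dropped). Note that for nested models this
  penalty admits the quadratic term spuriously with the usual asymptotic
  probability P(χ²₁ > 2) ≈ 16%; selecting the true linear model "≥ 90% of
  the time" is not achievable by plain AIC regardless of signal strength,
  so degree-selection performance is assessed where it is signal-limited —
  recovering a genuinely quadratic generator.
* **|Δβ_herb| (models C/D):** because gradient contrasts are estimates, the
  response carries a known sampling SE. Negative contrasts are folded:
  the response is `|Δβ|` and its sampling variance is recomputed as the
  variance of the folded normal `|X|, X ~ N(Δβ, SE²)` —
  `E|X| = σ√(2/π)·e^(−μ²/2σ²) + μ(1 − 2Φ(−μ/σ))`,
  `Var|X| = μ² + σ² − E|X|²`. Folding never increases the sampling SE.
  The model is hierarchical: `y_j ~ N(θ_j, se_j²)` with `se_j` fixed,
  `θ_j ~ N(c0 + c1 x_j [+ c2 x_j²], σ²_resid)`, priors
  `c ~ N(0, 10⁸ I)` and `σ²_resid ~ IG(0.001, 0.001)` (both configurable).

### Gibbs sampler

All full conditionals are conjugate. The coefficients are drawn *blocked*
with the latent means integrated out — `c | σ², y` is the weighted
least-squares Gaussian with weights `1/(σ² + se_j²)` — then
`θ | c, σ², y`, then `σ² | θ, c`. The naive one-at-a-time scan is avoided
deliberately: as `σ² → 0` (points with little residual scatter) the chain
θ ↔ c mixes arbitrarily slowly, while the blocked update remains exact.
Points with `se_j = 0` pin `θ_j = y_j`. Defaults are 2 chains × 13,000
iterations, 3,000 burn-in, thinning 10; split-R̂ and bulk ESS are reported
(via ArviZ) and R̂ > 1.1 attaches a convergence warning. Runs are exactly
reproducible given a seed. The sampler is validated in the test suite
against the exact posterior computed by quadrature over `σ²` with the
coefficients marginalized analytically.

### DIC

DIC uses the Spiegelhalter construction `DIC = D̄ + p_D`,
`p_D = D̄ − D(posterior means)`. The deviance is evaluated on the
*marginal* likelihood `y_j ~ N(Xc, σ²_resid + se_j²)` (latent means
integrated out). This is a deliberate choice of focus: the unit-level
(conditional) deviance barely discriminates regression degree because the
latent means absorb any lack of fit of the fixed effects, whereas the
marginal focus directly penalizes the regression structure being compared.

### Vertex

For quadratic fits with `c2 ≠ 0` the turning point is `x* = −c1/(2c2)`,
flagged as a maximum when `c2 < 0` — the herbivory intensity at which the
response peaks. The two reference coefficient sets used across the tests,
`(0.135, 5.4429, −6.3298)` and `(−0.206, 2.1713, −2.9216)`, have vertices
0.42994 and 0.37156.

## Synthetic study generator

The generator emulates the paired design so every stage is testable without
field data. Defaults mirror the study scale: 11 populations, 60–125 pairs
each (drawn per population), flowering start ~ N(180, 8²) days rounded to
integers, flower number negative-binomial with mean 18 and SD 6 (floored at
1 — marked plants flowered), corolla ~ N(28, 3²) mm.

Mechanism, per plant: the per-flower attack probability is
`logistic(baseline_pop + b_flowers·z_flowers + b_start·z_start +
b_corolla·z_corolla)` with traits standardized by their generative moments;
damage counts are binomial over flowers. In the HE arm the attack
probability is multiplied by `1 − exclusion_fidelity` (default 1.0 —
perfect exclusion, matching a protocol of manual removal every two days).
Undamaged flowers set fruit with probability 0.7; damaged flowers with
`0.7 × (1 − damage_fitness_cost)` (default cost 0.8 — the dominant
herbivore consumes ovaries, so a damaged flower loses most of its chance of
fruiting). Total seeds are gamma–Poisson around
`n_fruits × 50` (shape 5), giving realistic overdispersion. The default
preference `(b_flowers, b_start, b_corolla) = (0.5, 0.3, 0)` encodes
herbivores that prefer many-flowered, later-flowering plants and ignore
corolla size. Population baselines are spaced so that mean HP intensities
span 0.154–0.557 (`linear` scenario — the empirically observed range) or
0.10–0.65 (`nonlinear` scenario, wide enough that a quadratic
intensity–selection relation is identifiable). A per-population RNG stream
(spawned from the run seed) makes each population's records invariant to
how many populations the run contains.

What the generator does *not* emulate: pollinator behaviour, spatial attack
structure, within-pair environmental correlation, year effects, and any
trait–trait correlation. Per-flower seed loss severity (total vs partial
damage) is folded into the single multiplicative `damage_fitness_cost`
because the field protocol did not distinguish severities; the cost value
is a modelling choice, not an estimate. Passing tests therefore demonstrate
that the inference chain recovers the truth of *this* mechanism at the
study's design scale — not that the field system satisfies the OLS error
model.

### Known calibration properties

Seed set is mechanically proportional to flower number with multiplicative
(gamma–Poisson) noise, so the residual variance of relative fitness grows
with `z_flowers`. Least-squares tests involving the flower-number slope
inherit this heteroskedasticity and are mildly anticonservative (measured
~9% rejections at nominal 5% for the trait × population × treatment term
under a no-preference null); the same tests for flowering start and corolla
size — traits with no mechanical fitness link — are correctly calibrated
(KS-uniform over 500 null replicates). This is a property of least-squares
selection analysis applied to count fitness, and would apply equally to
real data.

Because the Bayesian meta-model estimates a residual variance that the
meta-point generator does not contain (points scatter only by their known
sampling SE), the posterior for `σ²_resid` retains mass away from zero at
n = 11 and credible intervals are wider than the error-free optimum;
measured coverage of the generating coefficients is ~98–100% rather than
the nominal 95%. The sampler itself is exact (validated against
quadrature); the conservatism is structural to fitting a
residual-variance term on 11 points that have none.

## Problem sizes and tolerances

Replicate counts used by the test suite and the acceptance script: 500
replicates for null calibration and for credible-interval coverage, 300 for
AIC degree selection, 150 for DIC degree selection (shorter single chains,
3,000 iterations, are used inside replicate loops; single fits use the full
default chains). Closed-form identities are checked to 1e-10, quadrature
agreement to 1e-8, oracle agreement to 1e-8, and Monte-Carlo quantities to
3–4 standard errors. Numeric pipeline outputs are serialized at 10
significant digits, making byte-identical reruns meaningful.

## Scope

Out of scope by design: pollinator-mediated selection, male fitness
components, floral-morph (distyly) analyses, cross-product quadratic
gradients `γ_ij`, mixed-effects models (population is a fixed factor
throughout), model averaging, and splines/GAMs.
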