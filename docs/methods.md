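# Methods

## Model and assumptions

`careclass` fits a two-level (nonparametric random-effect) latent class
model. Countries carry a discrete latent class W_j with shares π_m; women
carry a discrete latent class C_i whose distribution τ_{k|m} depends only on
their country's class; the H binary service indicators are conditionally
independent Bernoulli(ρ_{hk}) given C_i. The key assumptions are

- *local independence*: indicators are independent given the individual
  class (no residual pairwise dependence is modelled);
- *discrete country heterogeneity*: between-country variation in class
  composition is captured by M support points rather than a continuous
  random effect;
- *exchangeability within country*: all women in a country share W_j.

Missing indicator cells are handled by likelihood-factor omission, which is
valid when missingness is at random given the latent class; chained-equation
imputation (`prep.chained_impute`) is the alternative route for covariate or
non-ignorable patterns — the two are not combined in one analysis.

Record weights enter as frequency weights on log-likelihood contributions
and M-step sufficient statistics. Weighted and unweighted fits are both
supported; weighted is the default whenever the data carry weights. π_m is
estimated as the unweighted mean of group posteriors — each country counts
once, matching the generative model in which W_j is drawn per country.

## Estimation

**EM.** E-steps compute, in log space throughout (log-sum-exp over k per
record and over m per group), the group posteriors P_jm, the conditional
individual posteriors P(C=k|m, y_i), and their joint; M-steps are
closed-form weighted means. The weighted log-likelihood is non-decreasing
every iteration (asserted in tests). Defaults: 20 random restarts
(ρ initialized from perturbed overall indicator means, π and τ from
symmetric Dirichlet draws), relative log-likelihood tolerance 1e-8, maximum
1000 iterations. ρ is clamped to [1e-6, 1−1e-6] to keep log-likelihoods
finite. Label switching is resolved by a canonical ordering: individual
classes by descending mean ρ (ties: first indicator), then country classes
by descending τ in the optimal class (ties: larger π). MAP ties break toward
the lower class index.

**Class enumeration.** p = (M−1) + M(K−1) + K·H parameters. AIC = −2ℓ + 2p;
BIC uses log n at the individual level and log J at the country level;
ICL-BIC adds twice the summed entropy of the group posteriors to the
high-level BIC, so the two coincide exactly when countries are classified
with certainty. Selection is sequential: sweep K at M=1 (BIC_low), sweep M
at K* (BIC_high), re-check K at M*. Normalized entropy at the higher level
sums over groups with denominator J·log M; a `per_individual` flag restores
the variant that weights each group by its record count. Natural logs are
used everywhere (the normalization cancels the base).

**Two-step structural regressions.** With ρ fixed at the measurement
estimates, the same mixture likelihood is maximized over multinomial
logistic coefficients for country-class membership (design Z1, one row per
country) and individual-class membership (design Z2), the latter estimated
separately per country class because the reporting contract stratifies
odds ratios by coverage regime. The inner solver is Newton–Raphson with a
1e-6 ridge; coefficients beyond ±15 on the logit scale are flagged as
separation. The reference category is always the canonical
suboptimal/low-coverage class, so AOR > 1 means higher odds of optimal
utilization. Wald covariances come from the numerical observed information
(central differences, step 1e-4) of the step-2 likelihood at the optimum;
step-1 uncertainty is ignored — the standard naive two-step variance — and a
country-level nonparametric bootstrap is the conservative alternative. In a
null-effect simulation (200 simulate-and-refit replicates, 24 countries ×
125 women) the naive 95% CIs cover at about 93%, the expected mild
undercoverage of this trade-off.

**Random-intercept logistic.** Fitted by adaptive Gauss–Hermite quadrature:
per group the integral over the intercept is centered at the posterior mode
(vectorized Newton across groups) and scaled by the curvature there, with 15
Hermite nodes by default (doubling the nodes moves the log-likelihood by
<1e-3 in tests; the implementation matches `lme4::glmer` at nAGQ=15 to ~1e-3
on shared data). Optimization is BFGS over (β, log σ); the σ² CI is Wald on
the log-variance scale. ICC = σ²/(σ²+π²/3) uses the standard-logistic
residual variance; MOR = exp(√(2σ²)·Φ⁻¹(0.75)). Note that applying the MOR
closed form to a variance rounded to 1.10 gives 2.72; published tables that
pair 1.10 with an MOR of 2.76 presumably computed from the unrounded
variance, and this package always reports the closed form of the estimate it
has.

## Inequality measures

The outcome is the posterior probability of the optimal class (a flag
switches to the hard MAP indicator for comparison). Per dimension:

- difference y_adv − y_dis and ratio y_adv/y_dis for binary dimensions
  (residence, occupation);
- concentration indices on grouped data with midpoint cumulative ranks
  x_g = Σ_{g'<g} p_{g'} + p_g/2: RCI = (2/μ)Σ p_g y_g x_g − 1, ACI = μ·RCI
  (identity ACI = μ·RCI holds exactly by construction);
- SII/RII from a regression of subgroup means on x_g weighted by population
  shares, logit link by default (the outcome is a probability, so
  predictions at rank 0 and 1 stay in (0,1)); identity link available;
- PAR = max(y_ref − μ, 0) with the best-performing subgroup as default
  reference, PAF = 100·PAR/μ.

Ordered dimensions and their orientation are stated by the caller (wealth
poorest→richest, education none→higher). CIs are percentile bootstrap over
countries resampled with replacement (default B = 1000), reflecting
clustering of outcomes at the national level; replicates where a measure is
undefined (e.g., a subgroup absent from the resample) are dropped.

## Synthetic generator

The generator emulates a multi-country DHS-like survey: J countries (equal
sizes, explicit per-group sizes, or log-normal sizes with σ = 0.5 scaled to
a requested mean — country sizes in real surveys are data, not parameters),
a 2-class country level and 2-class individual level with the published
class profile as defaults (π = 0.656/0.344; τ rows 0.827/0.173 and
0.465/0.535; the eleven published optimal/suboptimal item-probability pairs).
The tetanus-toxoid pair is not published anywhere; (0.55, 0.30) is a free
default chosen to sit between the antenatal-care and facility-care
contrasts, and is never treated as ground truth. Optional multinomial
logistic covariate effects replace π/τ at either level; optional
gamma-distributed weights (shape 4, mean 1) mimic survey-weight spread;
missingness can be injected MCAR or MAR-on-a-covariate through a logistic
rule centered at the requested rate. One integer seed is split via
`SeedSequence.spawn` into independent streams (sizes, country classes,
individual classes, indicators, covariates, weights), so identical configs
are bit-identical.

What the generator does *not* emulate: two-stage cluster sampling geometry
(strata/PSUs), spatial structure, local dependence between indicators, or
item-specific nonresponse mechanisms. Passing recovery tests therefore
demonstrates correctness of the estimator under the model's own assumptions,
not robustness to the design effects of real surveys.

## Data preparation

Harmonization rules: antenatal care = 1 iff visits ≥ 4 for surveys before
2017 and ≥ 8 from 2017 on (the WHO guideline change); tetanus ≥ 2 doses;
DPT and polio ≥ 3 doses; the remaining flags (including age-appropriate
breastfeeding, which arrives pre-coded — no operational formula is imposed)
pass through; missing inputs propagate. Records with unparseable survey
years are retained with antenatal care missing and listed in an error
report. Continuous country covariates are z-scored, with the constants
emitted for back-transformation. Chained-equation imputation defaults: 10
cycles, m = 5 completed datasets, visit order by increasing missingness,
logistic models with Bernoulli predictive draws; observed cells are never
altered. Downstream, class models are fitted per completed dataset and
proportions averaged; Rubin-style pooling applies to structural
coefficients only.

## Problem sizes and numerical choices

Recovery experiments use 30 countries × 500 women (N = 15,000), where the
optimal-class facility-delivery and skilled-attendance probabilities are
recovered within ±0.01 of their generating values (0.97, 0.98) and MAP
agreement with truth exceeds 95% at both levels. Selection and sensitivity
demonstrations use 20 × 150; the null-coverage simulation uses 200
replicates of 24 × 125 — sizes chosen so the full validation suite runs
comfortably on a single CPU while keeping Monte-Carlo error well inside the
asserted tolerances. The brute-force check of the EM maximizer uses a
coarse-to-fine lattice ((τ, ρ) on a 0.05 grid, then 0.01 refinement around
the incumbent, τ always on a 0.01 grid), which lower-bounds the global
maximum; the EM solution is required not to fall below it.

## Known limitations

- Two-step standard errors ignore measurement-step uncertainty (mild CI
  undercoverage, quantified above); the country bootstrap is the remedy.
- No local-dependence modelling; strongly correlated indicator pairs will
  inflate apparent class separation.
- The higher level is strictly discrete; a continuous random-effect variant
  is out of scope.
- No design-based (strata/PSU) variance estimation; weights are treated as
  frequency weights.
- Indicators with weak class contrast (e.g., breastfeeding at 0.66 vs 0.63)
  contribute little information; subset models built mostly from such
  indicators classify individuals less consistently with the full model, as
  the sensitivity-analysis ARI column makes visible.
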