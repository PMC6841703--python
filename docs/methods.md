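# Methods

This note records the models implemented in `primingkit`, the numerical
choices behind them, and what the synthetic-data tests do and do not
demonstrate.

## Units and conversions

All computation runs on CO₂-C mass fluxes (μg C g⁻¹ dry soil d⁻¹) and
absolute isotope abundance (atom% ¹³C). Concentrations (mmol CO₂ mol⁻¹
headspace) and δ¹³C (‰ vs VPDB) are converted at ingest only.

* δ → atom%: `at% = 100·R/(1+R)`, `R = R_VPDB(δ/1000 + 1)`, with
  `R_VPDB = 0.0111802` by default (0.011237 is also in circulation;
  the constant is configurable). The round trip is exact to 1e−12.
* Concentration → flux uses the ideal gas law at the incubation
  temperature (15 °C default) and 1 atm with a configurable headspace
  volume (0.25 L default) and soil mass (20 g default), normalized by
  the gas-accumulation window. Accumulation windows may differ by day
  (2 h on days 1–8, 8 h on days 15–65 by default, when fluxes are low).
  Bottle pressure, headspace volume and the exact conversion route are
  conventions of this package, stated here because incubation papers
  rarely print them.
* Blank bottles that lack an isotope measurement are assigned
  1.08 atom% (natural-abundance vicinity), configurable.

## Partitioning and priming

Blank correction, two-endmember mixing and the priming difference are
implemented exactly as in the README's equations. Points worth noting:

* The SOM endmember `at%_SOM` defaults to the blank-corrected
  control-soil respiration atom% of the same site and day; a per-site
  override is supported. This treats control respiration as pure
  SOM-derived CO₂, which is exactly true in the absence of label.
* Replicates are aggregated (mean per site × treatment × day) before
  mixing; a per-replicate mode exists for diagnostics and supplies the
  spread of `f_SOM` used in error propagation.
* Glucose fractions pushed outside [0, 1] by noise near natural
  abundance are clamped with a logged flag rather than failing: at late
  timepoints the label signal is comparable to instrument noise and
  slightly negative fractions are routine.
* Cumulative values use the trapezoid across measured days plus a
  leading rectangle from day 0 to day 1 at the day-1 rate (toggleable
  via `IncubationDesign.include_day0_rectangle`), so the default covers
  the full 65-day window. Whether the original integration began at
  day 0 or day 1 is not documented; both options are first-class.
* Carbonate-derived CO₂ is not corrected for (it is known to contribute
  ~1% in comparable alkaline-soil experiments); an override of the SOM
  endmember is the hook if a correction is ever needed.

## Monte-Carlo confidence interval

Per site and day, the SD of the treated SOM-derived flux combines the
relative SDs of `C_treat` and `f_SOM` in quadrature and is multiplied
by the mean SOM-derived flux (the quadrature expression is a relative
SD; the implementation states this reading explicitly). Control-flux
SDs come directly from the triplicates. Each of the 1000 draws samples
per-day treatment and control SOM fluxes independently from normal
distributions, differences them, and integrates; the 2.5/97.5
percentiles over draws give the CI.

Calibration choice: the sampler uses the **standard error of the
replicate mean** (SD/√n), not the raw replicate SD. The point estimate
being bracketed is built from replicate means, so a calibrated interval
must describe the sampling distribution of those means; sampling with
the raw SD would inflate the interval by ~√3 under triplicates. The
empirical-coverage test (200 re-measured datasets of one site) checks
this calibration against the exact binomial band around 95%.

Assumptions: errors are independent across days (no temporal
autocorrelation) and across the two treatment arms; draws may be
negative (no truncation, which would bias the interval). One root seed
spawns per-site streams keyed by a CRC of the site id, so site order
cannot change results.

## Two-pool model inversion

`R(t) = k₁f₁C_tot·e^(−k₁t) + k₂(1−f₁)C_tot·e^(−k₂t)` is fit to
control rates normalized per g SOC, with `C_tot = 1000 mg C g⁻¹ SOC` so
pool sizes read as percent of SOC. A two-pool (not three-pool) form is
used deliberately: a 65-day incubation cannot constrain a passive pool.

* **Priors**: uniform, `f₁ ∈ [1e−4, 0.5]`, `k₁ ∈ [0.005, 1] d⁻¹`,
  `k₂ ∈ [1e−6, 0.005] d⁻¹`, overridable; the support additionally
  enforces `k₁ > k₂` (identifiability guard against label switching).
* **Noise model**: by default the Gaussian noise scale is a free
  parameter under a Jeffreys prior, marginalized analytically
  (posterior ∝ SSR^(−n/2) over the prior box). A fixed absolute or
  relative noise mode is available; with only six observations and
  three parameters, the marginal mode tends to be overconfident about
  the weakly identified k₂ (three residual degrees of freedom do not
  estimate a variance well), so analyses that know the measurement
  error level should pass it explicitly — the recovery tests do.
* **Sampler**: 3 chains of random-walk Metropolis in a transformed
  space (linear logit for f₁, log-scale logit for k₁/k₂, with the
  Jacobian in the target so priors stay uniform on the original scale).
  Each iteration does a component-wise sweep with per-parameter
  adaptive scales plus one joint proposal whose covariance is estimated
  from pooled burn-in history (scaled 2.38²/d) — the posterior is a
  correlated ridge that axis-aligned steps traverse too slowly. The
  first 50% of iterations is burn-in; all adaptation stops there.
  Defaults are 3 × 50,000 iterations; the test suite and acceptance
  script use 3 × 10,000, which the convergence diagnostics support.
* **Summaries**: MAP is the highest-posterior retained draw. A
  parameter is *well constrained* when its 95% interval occupies <80%
  of the prior range and the MAP sits in the central 90% of the prior;
  well-constrained parameters report the MAP, others the posterior
  mean. Convergence uses the classic split-chain Gelman–Rubin factor
  (clamped at 1 from below); an independent arviz computation
  cross-checks it in the tests. Acceptance below 1% raises rather than
  returning garbage.

## Driver statistics

* **Partial correlation**: Pearson correlation of OLS residuals after
  regressing both variables on the controls (with intercept);
  significance via `t = r√(df/(1−r²))`, `df = n − 2 − q`. Controls are
  applied one at a time by default (matching how per-factor dependency
  is usually displayed); listwise deletion handles missing values, and
  n is reported per pair. No multiple-testing adjustment is applied by
  default, matching the raw-p convention of transect studies of this
  size.
* **Coefficient change**: `100·(|r₀| − |r_c|)/|r₀|`; negative values
  flag gained correlation; undefined (NaN) when `r₀ = 0`.
* **Variation partitioning**: all 15 subset OLS models over the four
  groups, Ezekiel-adjusted R² each, and the exclusive fraction of every
  subset obtained by solving the inclusion–exclusion linear system
  (15×15; exact, and verified against the closed form for two groups).
  Raw fractions sum to the full-model adjusted R² by construction;
  negative fractions are reported raw and truncated to zero in the
  headline table with a flag — a group explaining less than random
  noise explains nothing. Partitioning is multiple-regression-based
  (single response), not RDA-based.
* **Group PC1**: leading eigenvector of the correlation matrix of the
  standardized site × variable block, sign-oriented to correlate
  positively with the block's first column. This is the preparation
  step feeding structural equation modelling; SEM itself is out of
  scope here.

## Synthetic transect generator

The generator emulates the study design — 30 sites (18 steppe,
12 meadow by precipitation rank), triplicate control and glucose
bottles, five shared blanks, days {1, 3, 8, 15, 35, 65} at 15 °C,
glucose at 3.0 atom% dosed at 100% of MBC — with a forward model chosen
to make every stage invertible:

* Covariates are drawn along a precipitation gradient (89–534 mm) with
  SOC ∈ [1.1, 118] g kg⁻¹ and MBC ∈ [23, 1101] mg kg⁻¹ interpolated on
  a log scale (right-skewed, as observed), pH ∈ [6.2, 9.4] declining
  with wetness, and four covariate groups of 5–8 variables with
  plausible cross-correlations. Range bounds are enforced by
  construction.
* True priming is an exponentially decaying multiplier on SOM-derived
  flux under treatment: `π₀·e^(−λt)`, with λ ∈ [0.02, 0.05] d⁻¹. The
  amplitude follows a stated linear model,
  `π₀ = 0.45 + 0.30·z(recalcitrant_pool) − 0.20·z(feal_soc) + ε`,
  `ε ~ N(0, 0.15)`, clipped to (−0.9, 1.5) — so the driver screen has a
  known signal (recalcitrance raises priming, mineral protection lowers
  it) and relative priming spans suppression to ~130% of basal
  respiration. The exponential form makes cumulative truth analytic
  (verified against adaptive quadrature to 0.1%).
* Glucose-derived flux is first-order, `dose·φ·k_g·e^(−k_g t)` with
  φ = 0.6 and k_g = 0.3 d⁻¹ (fast turnover conventions, not measured
  claims). Bottle isotope composition mixes the SOM endmember
  (1.08 atom%) and the glucose endmember exactly, flux-weighted, then
  folds in ambient blank CO₂ (0.05 mmol mol⁻¹) so the blank correction
  is nontrivial.
* Noise defaults: 5% relative on respired fluxes, 0.005 atom% absolute
  on isotope compositions, independent per bottle.

**What the synthetic tests show**: that the implementation inverts its
own forward model exactly without noise, that the CI machinery is
calibrated under the stated noise model, and that parameter and signal
recovery behave as theory predicts. **What they do not show**: anything
about real soils — real incubations have temporally correlated errors,
non-Gaussian instrument noise, carbonate interference, apparent isotope
fractionation, and priming dynamics that need not decay exponentially.

## Degenerate inputs and tie-breaks

Endmembers closer than 1e−6 atom% raise a partition error; bottle CO₂
at or below blank raises rather than producing negative fluxes (with a
small tolerance band flagged as zero); zero control flux makes relative
priming undefined (None) while absolute priming is still reported;
single replicates yield mean-only cells with SD flagged unavailable;
zero observation variance makes R² NaN with RMSE still defined.

## Problem sizes

Default analyses use the 30-site transect with 6 measurement days and
1000 Monte-Carlo draws. The test suite runs two-pool inversions at
3 × 10,000 iterations and CI coverage at 200 replicate datasets; these
sizes give stable diagnostics (R̂ < 1.1, percentile endpoints stable to
<2% of interval width) while keeping a full run to minutes.
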