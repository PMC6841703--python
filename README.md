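# primingkit

Quantitative toolkit for **soil priming-effect studies** built on
¹³C-glucose labelling: isotope source partitioning of respired CO₂,
Monte-Carlo uncertainty on the cumulative priming effect, two-pool
decomposition-model inversion by MCMC, and the driver-screening
statistics used to ask *which* soil properties control priming across a
transect. It is written for biogeochemists running laboratory
incubations of labelled soils, and ships a synthetic incubation-transect
generator with known ground truth so the whole chain is testable without
any measured data.

## The science in brief

A labile C input (here glucose labelled at 3.0 atom% ¹³C, dosed at 100%
of microbial biomass C) can accelerate or suppress the decomposition of
native soil organic matter (SOM) — the *priming effect*. With the bottle
(`soil`) and blank CO₂ measurements, the analysis proceeds:

1. **Blank correction** of the isotope composition of respired CO₂:
   `at%_respired = (at%_soil·C_soil − at%_blank·C_blank)/(C_soil − C_blank)`.
2. **Two-endmember partitioning** between glucose and SOM:
   `f_glucose = (at%_treat − at%_SOM)/(at%_glucose − at%_SOM)`,
   `f_glucose + f_SOM = 1`.
3. **Priming effect** per measurement day:
   `PE = C_treat·f_SOM − C_control`, and relative priming
   `= 100·PE/C_control` (% of basal respiration). Cumulative priming is
   the trapezoidal integral over the incubation (days 1, 3, 8, 15, 35,
   65 by default), with a leading day-0 rectangle.
4. **Uncertainty**: the SD of the treatment SOM-derived flux combines
   flux and isotope-fraction errors in quadrature,
   `σ/μ = √((σ_Ctreat/C_treat)² + (σ_fSOM/f_SOM)²)`; 1000 Monte-Carlo
   draws of the per-day fluxes give a percentile 95% CI on the
   cumulative priming.
5. **Two-pool model**: control rates per g SOC follow
   `R(t) = k₁f₁C_tot·e^(−k₁t) + k₂(1−f₁)C_tot·e^(−k₂t)` with
   `C_tot = 1000 mg C g⁻¹ SOC`; (f₁, k₁, k₂) are estimated by
   random-walk Metropolis under uniform priors, reporting MAP for
   well-constrained and posterior means for poorly constrained
   parameters, plus R²/RMSE and Gelman–Rubin diagnostics.
6. **Drivers**: zero-order vs controlled partial correlations (with the
   % change in coefficient), variation partitioning of adjusted R²
   across the plant / soil / microbial / SOM-stability covariate groups
   (negative unique fractions truncated to zero), and per-group PC1
   extraction.

## Worked example

```sh
python examples/01_partition_single_site.py
```

```
site S01: true priming amplitude pi0 = 0.422, decay 0.034 d^-1

 day  f_glucose  c_treat  c_control  priming  relative_priming
 1.0      0.053  665.289    442.832  187.307            42.298
 3.0      0.040  430.201    293.147  119.658            40.818
 8.0      0.022  184.333    138.414   41.836            30.226
15.0      0.009   70.640     55.726   14.292            25.647
35.0      0.000   30.943     29.242    1.701             5.818
65.0      0.000   29.853     27.783    2.070             7.452
```

`f_glucose` is the fraction of treated-soil CO₂ carrying the glucose
label (large early, gone by day 35); `priming` is the extra SOM-derived
CO₂ relative to the control in μg C g⁻¹ d⁻¹, here ~40% of basal
respiration early on and decaying — consistent with the generator's
true amplitude of 0.422.

The other examples cover the Monte-Carlo CI (`02`), the two-pool
inversion with its constraint classification (`03`), the driver screen
(`04`), and the reproducible end-to-end pipeline (`05`). The same
stages are available from the shell:

```sh
primingkit run-all --out-dir results/ --seed 42
primingkit simulate --n-sites 30 --seed 42 --out-dir fixtures/
primingkit partition --incubation fixtures/incubation.csv --out part.csv
```

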