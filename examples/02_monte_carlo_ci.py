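"""Monte-Carlo 95% confidence interval for cumulative priming.

Propagates replicate scatter in fluxes and isotope fractions through
1000 draws of the per-day SOM-derived fluxes, integrating each draw.
"""

from primingkit import (
    IncubationDesign,
    generate_transect,
    monte_carlo_priming,
    partition_sites,
    simulate_incubation,
    uncertainty_inputs,
)

design = IncubationDesign()
truth = generate_transect(1, seed=3)[0]
records = simulate_incubation(truth, design, seed=3)
part = partition_sites(records, design, per_replicate=True)

ci = monte_carlo_priming(uncertainty_inputs(part), design,
                         n_draws=1000, seed=3)
true_cum = truth.cumulative_priming_analytic(design.schedule[-1])

print(f"site {ci.site_id}")
print(f"  cumulative priming estimate: {ci.point_estimate:8.1f} ug C/g")
print(f"  95% CI (percentile, n={ci.n_draws}): "
      f"[{ci.ci_low:.1f}, {ci.ci_high:.1f}]")
print(f"  generator truth:             {true_cum:8.1f} ug C/g")
print(
    "\nThe interval reflects triplicate measurement scatter propagated "
    "through source partitioning and time integration; the known truth "
    "should fall inside it ~95% of the time."
)
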