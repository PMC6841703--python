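"""Screen which covariate group drives the priming effect.

Generates a 30-site transect whose priming amplitude depends on SOM
recalcitrance (+) and mineral protection (-), runs the full pipeline to
the per-site cumulative priming, then partial correlations and
variation partitioning across the four covariate groups.
"""

import tempfile

import pandas as pd

from primingkit import run_all

with tempfile.TemporaryDirectory() as tmp:
    run_all(tmp, n_sites=30, seed=42, n_draws=500, mcmc_iter=2000)
    varpart = pd.read_csv(f"{tmp}/varpart_relative.csv")
    change = pd.read_csv(f"{tmp}/coefficient_change.csv")

print("variation partitioning of relative priming (unique fractions):")
uniq = varpart[~varpart["fraction"].str.contains(r"\+|residual")]
print(uniq[["fraction", "raw", "truncated"]].round(4).to_string(index=False))

# percent change is only meaningful for associations that existed at all
strong = change[change["r_zero"].abs() > 0.3]
top = strong.reindex(strong["pct_change"]
                     .sort_values(ascending=False).index).head(5)
print("\nlargest coefficient losses when controlling SOM stability "
      "(among |r_zero| > 0.3):")
print(top[["x_var", "control", "r_zero", "r_controlled", "pct_change"]]
      .round(3).to_string(index=False))
print(
    "\nA large positive pct_change means the zero-order association of "
    "that variable with priming largely rides on the controlled SOM-"
    "stability variable — the generator built the signal into "
    "recalcitrant_pool and feal_soc, which the screen recovers."
)
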