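"""One reproducible end-to-end run: simulate -> partition -> CI ->
two-pool inversion -> drivers, with a manifest of hashed outputs."""

import json
from pathlib import Path

from primingkit import run_all

out = Path("pipeline_demo")
manifest = run_all(out, n_sites=30, seed=42, n_draws=1000, mcmc_iter=5000)

summary = json.loads((out / "summary.json").read_text())
print(f"outputs written under {out}/ ({len(manifest['outputs'])} files)")
print(f"max relative priming: "
      f"{summary['max_relative_priming_pct']:.1f}% of basal respiration")
print(f"two-pool fit: median R2 = {summary['twopool']['median_r2']:.3f}, "
      f"median RMSE = {summary['twopool']['median_rmse']:.3f}")
print("unique variance in relative priming by group (%):")
for grp, val in summary["drivers"]["unique_fraction_relative_pct"].items():
    print(f"  {grp:>14}: {val:5.1f}")
print(
    "\nRe-running with the same seed reproduces summary.json and all "
    "output hashes byte-for-byte (see manifest.json)."
)
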