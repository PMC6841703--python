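"""End-to-end orchestration: simulate -> partition -> CI -> two-pool -> drivers.

``run_all`` is pure composition over the stage functions; every stage
writes its CSV before the next starts, so a failure leaves earlier
outputs intact.  A manifest records the configuration snapshot, seeds
and SHA-256 hashes of every output for reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    Constants,
    IncubationDesign,
    covariates_to_wide,
    load_config,
    read_covariates_table,
    read_incubation_table,
)
from .drivers import drivers_screen
from .partitioning import cumulative_by_site, partition_sites
from .synthetic_data import (
    TransectConfig,
    generate_transect,
    simulate_transect,
    write_fixtures,
)
from .twopool import mcmc_fit
from .uncertainty import monte_carlo_all_sites

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def stage_partition(
    incubation_path: Path,
    design: IncubationDesign,
    constants: Constants,
    out_path: Path,
) -> pd.DataFrame:
    records = read_incubation_table(incubation_path, design, constants)
    part = partition_sites(records, design, constants, per_replicate=True)
    _write_csv(part, out_path)
    return part


def stage_priming_ci(
    partition: pd.DataFrame,
    design: IncubationDesign,
    out_path: Path,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    ci = monte_carlo_all_sites(partition, design, n_draws=n_draws, seed=seed)
    cum = cumulative_by_site(partition, design)
    ci = ci.merge(cum, on="site_id")
    _write_csv(ci, out_path)
    return ci


def stage_twopool(
    partition: pd.DataFrame,
    soc_by_site: pd.Series,
    out_path: Path,
    n_chains: int = 3,
    n_iter: int = 50_000,
    seed: int = 0,
    priors: dict | None = None,
) -> pd.DataFrame:
    """Fit the two-pool model to each site's control rates (per g SOC)."""
    rows = []
    root = np.random.SeedSequence(seed)
    for i, (site, sub) in enumerate(partition.groupby("site_id")):
        if site not in soc_by_site.index:
            raise KeyError(f"no SOC covariate for site {site}")
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(dtype=float)
        # ug C g-1 soil d-1  ->  mg C g-1 SOC d-1
        rates = sub["c_control"].to_numpy(dtype=float) / float(soc_by_site[site])
        child = int(root.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
        summ = mcmc_fit(days, rates, priors=priors, n_chains=n_chains,
                        n_iter=n_iter, seed=child)
        row = {"site_id": site, "r2": summ.r2, "rmse": summ.rmse,
               "acceptance_rate": summ.acceptance_rate}
        for p in ("f1", "k1", "k2"):
            row.update({
                f"{p}_map": summ.map_estimate[p],
                f"{p}_mean": summ.mean[p],
                f"{p}_q025": summ.q025[p],
                f"{p}_q975": summ.q975[p],
                f"{p}_point": summ.point_estimate[p],
                f"{p}_class": summ.constraint_class[p],
                f"{p}_rhat": summ.gelman_rubin[p],
            })
        rows.append(row)
    df = pd.DataFrame(rows)
    _write_csv(df, out_path)
    return df


def stage_drivers(
    covariates_path: Path,
    response: pd.Series,
    out_dir: Path,
    relative_response: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Driver screen on the absolute priming response (and, optionally,
    variation partitioning of the relative priming as well)."""
    covs = read_covariates_table(covariates_path)
    wide = covariates_to_wide(covs)
    results = drivers_screen(wide, response)
    for name in ("zero_order", "controlled", "coefficient_change",
                 "varpart", "pc1"):
        _write_csv(results[name],
                   out_dir / ("partial_corr.csv" if name == "zero_order"
                              else f"{name}.csv"))
    if relative_response is not None:
        rel = drivers_screen(wide, relative_response)
        results["varpart_relative"] = rel["varpart"]
        _write_csv(rel["varpart"], out_dir / "varpart_relative.csv")
    return results


def run_all(
    out_dir: str | Path,
    config_path: str | Path | None = None,
    incubation_path: str | Path | None = None,
    covariates_path: str | Path | None = None,
    simulate: bool = True,
    n_sites: int = 30,
    seed: int = 42,
    n_draws: int = 1000,
    mcmc_chains: int = 3,
    mcmc_iter: int = 50_000,
    transect_config: TransectConfig = TransectConfig(),
) -> dict:
    """Run every stage in order; returns the manifest dict.

    With ``simulate`` (default) a synthetic transect provides the
    inputs; otherwise ``incubation_path`` and ``covariates_path`` must
    point at existing tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config_path is not None:
        design, constants = load_config(config_path)
    else:
        design, constants = IncubationDesign(), Constants()

    seeds = {"root": seed, "simulate": seed, "monte_carlo": seed + 1,
             "mcmc": seed + 2}
    outputs: dict[str, Path] = {}

    if simulate:
        truths = generate_transect(n_sites, seed=seeds["simulate"],
                                   config=transect_config)
        records = simulate_transect(
            truths, design, seed=seeds["simulate"],
            flux_noise_rel=transect_config.flux_noise_rel,
            atom_pc_noise_abs=transect_config.atom_pc_noise_abs,
            blank_conc=transect_config.blank_conc_mmol_mol,
            constants=constants,
        )
        paths = write_fixtures(truths, records, out)
        incubation_path = paths["incubation"]
        covariates_path = paths["covariates"]
        outputs.update({k: p for k, p in paths.items()})
    else:
        if incubation_path is None or covariates_path is None:
            raise ValueError("without --simulate, provide incubation and "
                             "covariate tables")
        incubation_path = Path(incubation_path)
        covariates_path = Path(covariates_path)

    logger.info("stage: partition")
    part = stage_partition(incubation_path, design, constants,
                           out / "partition.csv")
    outputs["partition"] = out / "partition.csv"

    logger.info("stage: priming-ci")
    ci = stage_priming_ci(part, design, out / "priming_ci.csv",
                          n_draws=n_draws, seed=seeds["monte_carlo"])
    outputs["priming_ci"] = out / "priming_ci.csv"

    logger.info("stage: two-pool fit")
    covs = read_covariates_table(covariates_path)
    wide = covariates_to_wide(covs)
    soc = wide[("soil", "soc")]
    tp = stage_twopool(part, soc, out / "twopool_fit.csv",
                       n_chains=mcmc_chains, n_iter=mcmc_iter,
                       seed=seeds["mcmc"])
    outputs["twopool_fit"] = out / "twopool_fit.csv"

    logger.info("stage: drivers")
    response = ci.set_index("site_id")["point_estimate"]
    relative = ci.set_index("site_id")["cumulative_relative_priming"]
    drv = stage_drivers(covariates_path, response, out,
                        relative_response=relative)
    for name in ("controlled", "coefficient_change", "varpart",
                 "varpart_relative", "pc1"):
        outputs[name] = out / f"{name}.csv"
    outputs["partial_corr"] = out / "partial_corr.csv"

    # ------------------------------------------------------------------ summary
    varpart = drv["varpart"].set_index("fraction")
    summary = {
        "n_sites": int(part["site_id"].nunique()),
        "per_site": {
            r.site_id: {
                "cumulative_priming": r.point_estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "cumulative_relative_priming_pct": r.cumulative_relative_priming,
            }
            for r in ci.itertuples()
        },
        "max_relative_priming_pct": float(
            part["relative_priming"].max()
        ),
        "twopool": {
            "median_r2": float(tp["r2"].median()),
            "median_rmse": float(tp["rmse"].median()),
            "max_rhat": float(
                tp[[c for c in tp.columns if c.endswith("_rhat")]].max().max()
            ),
        },
        "drivers": {
            "unique_fraction_pct": {
                g: 100.0 * float(varpart.loc[g, "truncated"])
                for g in ("plant", "soil", "microbial", "som_stability")
            },
            "unique_fraction_relative_pct": {
                g: 100.0 * float(
                    drv["varpart_relative"].set_index("fraction")
                    .loc[g, "truncated"]
                )
                for g in ("plant", "soil", "microbial", "som_stability")
            },
            "pc1_variance_explained_pct": {
                g: float(s["variance_explained"].iloc[0])
                for g, s in drv["pc1"].groupby("group")
            },
            "mean_abs_coefficient_change_pct": float(
                drv["coefficient_change"]["pct_change"].abs().mean()
            ),
        },
        "warnings": {
            "clamped_fractions": int(part["clamped"].sum()),
            "truncated_varpart_fractions": int(
                drv["varpart"]["was_truncated"].sum()
            ),
        },
        "seeds": seeds,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = summary_path

    manifest = {
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seeds": seeds,
        "design": dataclasses.asdict(design),
        "constants": dataclasses.asdict(constants),
        "mcmc": {"chains": mcmc_chains, "iterations": mcmc_iter},
        "n_draws": n_draws,
        "outputs": {k: str(p) for k, p in outputs.items()},
        "hashes": {k: _sha256(p) for k, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
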