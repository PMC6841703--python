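"""Error propagation and Monte-Carlo confidence intervals for priming.

Per measurement day the SOM-derived flux under glucose treatment is
C_treat * f_SOM; its relative SD combines the flux and isotope-fraction
uncertainties in quadrature,

    sd / mean = sqrt((sd_Ctreat / C_treat)^2 + (sd_fSOM / f_SOM)^2),

treating the two as independent.  The Monte Carlo then draws the
SOM-derived fluxes of treatment and control independently per day from
normal distributions, differences them into a priming series,
integrates, and takes percentile bounds over the draws.

The spread fed to the sampler is the standard error of the replicate
mean (replicate SD / sqrt(n)): the cumulative estimate is built from
replicate means, so a calibrated interval must describe the sampling
distribution of those means, not single-bottle scatter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import IncubationDesign
from .partitioning import cumulative_priming


@dataclass
class PrimingCI:
    """Cumulative priming with a percentile Monte-Carlo 95% CI."""

    site_id: str
    cumulative_mean: float      # ug C g-1, mean over draws
    point_estimate: float       # ug C g-1, from the mean inputs
    ci_low: float               # 2.5 percentile
    ci_high: float              # 97.5 percentile
    n_draws: int
    seed: int


def som_flux_sd(
    sigma_ctreat: float,
    c_treat: float,
    sigma_fsom: float,
    f_som: float,
    som_flux_mean: float,
) -> float:
    """Quadrature error propagation for the treated SOM-derived flux."""
    if sigma_ctreat < 0 or sigma_fsom < 0:
        raise ValueError("standard deviations must be >= 0")
    if c_treat <= 0 or f_som <= 0:
        if sigma_ctreat == 0 and sigma_fsom == 0:
            return 0.0
        raise ValueError(
            "mean C_treat and f_SOM must be positive to form relative SDs"
        )
    rel = np.hypot(sigma_ctreat / c_treat, sigma_fsom / f_som)
    return som_flux_mean * rel


def uncertainty_inputs(partition: pd.DataFrame, use_sem: bool = True) -> pd.DataFrame:
    """Build per-(site, day) Monte-Carlo inputs from a partition table.

    Needs the per-replicate columns produced by
    ``partition_sites(..., per_replicate=True)``.  With ``use_sem`` the
    replicate SDs are scaled by 1/sqrt(n) to standard errors of the
    mean (default; see module docstring).
    """
    required = {"c_treat_sd", "c_control_sd", "f_som_sd", "n_treat", "n_control"}
    if not required.issubset(partition.columns):
        raise ValueError(
            "partition table lacks replicate-spread columns; rerun "
            "partition_sites with per_replicate=True"
        )
    df = partition.copy()
    scale_t = np.sqrt(df["n_treat"]) if use_sem else 1.0
    scale_c = np.sqrt(df["n_control"]) if use_sem else 1.0
    sd_ct = df["c_treat_sd"].fillna(0.0) / scale_t
    sd_fs = df["f_som_sd"].fillna(0.0) / scale_t
    out = pd.DataFrame({
        "site_id": df["site_id"],
        "day": df["day"],
        "som_treat_mean": df["som_flux_treat"],
        "som_treat_sd": [
            som_flux_sd(sc, ct, sf, fs, sm)
            for sc, ct, sf, fs, sm in zip(
                sd_ct, df["c_treat"], sd_fs, df["f_som"], df["som_flux_treat"]
            )
        ],
        "control_mean": df["c_control"],
        "control_sd": df["c_control_sd"].fillna(0.0) / scale_c,
    })
    return out


def monte_carlo_priming(
    inputs: pd.DataFrame,
    design: IncubationDesign,
    n_draws: int = 1000,
    seed: int = 0,
    site_id: str | None = None,
) -> PrimingCI:
    """Percentile 95% CI for one site's cumulative priming effect.

    ``inputs`` is the per-day frame from :func:`uncertainty_inputs`
    restricted to one site (or pass ``site_id`` to select).  Negative
    draws are permitted — truncation would bias the interval.
    Deterministic for a fixed seed.
    """
    if site_id is not None:
        inputs = inputs[inputs["site_id"] == site_id]
    sites = set(inputs["site_id"])
    if len(sites) != 1:
        raise ValueError(f"inputs must cover exactly one site, got {sites}")
    site = sites.pop()
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    sub = inputs.sort_values("day")
    days = sub["day"].to_numpy(dtype=float)
    mt = sub["som_treat_mean"].to_numpy(dtype=float)
    st = sub["som_treat_sd"].to_numpy(dtype=float)
    mc = sub["control_mean"].to_numpy(dtype=float)
    sc = sub["control_sd"].to_numpy(dtype=float)
    if np.any(st < 0) or np.any(sc < 0):
        raise ValueError("standard deviations must be >= 0")

    rng = np.random.default_rng(seed)
    treat = rng.normal(mt, st, size=(n_draws, days.size))
    control = rng.normal(mc, sc, size=(n_draws, days.size))
    priming = treat - control

    totals = np.trapezoid(priming, days, axis=1)
    if design.include_day0_rectangle and days[0] > 0:
        totals = totals + days[0] * priming[:, 0]
    lo, hi = np.percentile(totals, [2.5, 97.5])
    point = cumulative_priming(days, mt - mc, design.include_day0_rectangle)
    return PrimingCI(
        site_id=site,
        cumulative_mean=float(np.mean(totals)),
        point_estimate=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=n_draws,
        seed=seed,
    )


def monte_carlo_all_sites(
    partition: pd.DataFrame,
    design: IncubationDesign,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo CI per site; child seeds derived so site order is moot."""
    inputs = uncertainty_inputs(partition)
    rows = []
    root = np.random.SeedSequence(seed)
    for site in sorted(inputs["site_id"].unique()):
        # stable per-site stream independent of site ordering
        site_key = zlib.crc32(site.encode()) & 0x7FFFFFFF
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(site_key,))
        ci = monte_carlo_priming(
            inputs[inputs["site_id"] == site], design,
            n_draws=n_draws, seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
        )
        rows.append({
            "site_id": site,
            "cumulative_mean": ci.cumulative_mean,
            "point_estimate": ci.point_estimate,
            "ci_low": ci.ci_low,
            "ci_high": ci.ci_high,
            "n_draws": ci.n_draws,
            "seed": ci.seed,
        })
    return pd.DataFrame(rows)
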