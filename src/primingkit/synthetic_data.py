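"""Virtual incubation transect with known ground truth.

Emulates the study design end-to-end: 30 grassland sites (18 steppe,
12 meadow) along a precipitation gradient, control vs 13C-glucose
incubations in triplicate with five blank bottles, measurements on days
1, 3, 8, 15, 35 and 65 at 15 degC, glucose dosed at 100% of microbial
biomass C at 3.0 atom% 13C.

The forward model makes every pipeline stage invertible with known
truth:

* control SOM-derived flux comes from the site's two-pool parameters,
  scaled from per-g-SOC to per-g-soil by the site's SOC content;
* true priming is an exponentially decaying multiplier pi0 exp(-lam t)
  on the SOM-derived flux under treatment, so the cumulative priming
  has a closed form;
* glucose-derived flux is first-order: dose * phi * k_g exp(-k_g t);
* bottle isotope composition mixes the SOM and glucose endmembers
  exactly, flux-weighted, then folds in the blank (ambient) CO2 so the
  blank correction is exercised nontrivially.

The priming amplitude pi0 is a stated linear function of the site's
standardized recalcitrant-pool covariate (positive) and its mineral
protection covariate (negative) plus noise, so the driver statistics
have a known signal to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    Constants,
    IncubationDesign,
    MeasurementRecord,
    SiteCovariates,
    cflux_to_concentration,
    records_to_frame,
)
from .twopool import TwoPoolParams, two_pool_rate


@dataclass(frozen=True)
class TransectConfig:
    """Generator knobs: covariate ranges and the priming signal model."""

    # observed transect ranges the covariates must respect
    precip_range: tuple[float, float] = (89.0, 534.0)       # mm
    npp_range: tuple[float, float] = (38.0, 488.0)          # g m-2 yr-1
    soc_range: tuple[float, float] = (1.1, 118.0)           # g kg-1
    mbc_range: tuple[float, float] = (23.0, 1101.0)         # mg C kg-1
    ph_range: tuple[float, float] = (6.2, 9.4)

    # priming amplitude: pi0 = b0 + b_recal*z(recal) + b_protect*z(feal) + eps
    pi0_intercept: float = 0.45
    pi0_beta_recalcitrance: float = 0.30
    pi0_beta_protection: float = -0.20
    pi0_noise_sd: float = 0.15
    pi0_bounds: tuple[float, float] = (-0.9, 1.5)

    # priming decay and glucose kinetics
    priming_decay_range: tuple[float, float] = (0.02, 0.05)  # lam, d-1
    glucose_k: float = 0.3            # d-1
    glucose_mineralized: float = 0.6  # phi, fraction of dose respired

    # two-pool truth ranges (fast fraction, decay constants)
    f1_range: tuple[float, float] = (0.005, 0.05)
    k1_range: tuple[float, float] = (0.02, 0.3)
    k2_range: tuple[float, float] = (5e-5, 1e-3)

    som_atom_pc: float = 1.08         # natural-abundance vicinity
    blank_conc_mmol_mol: float = 0.05  # ambient CO2 in every bottle

    # measurement noise defaults
    flux_noise_rel: float = 0.05
    atom_pc_noise_abs: float = 0.005

    meadow_fraction: float = 0.4      # 12 of 30 sites


@dataclass
class SiteTruth:
    """Everything the generator knows about one site."""

    site_id: str
    ecosystem: str                   # steppe | meadow
    twopool: TwoPoolParams
    priming_amplitude: float         # pi0, fraction of SOM flux at t=0
    priming_decay: float             # lam, d-1
    glucose_dose: float              # ug C g-1 soil (= MBC)
    glucose_k: float                 # d-1
    glucose_mineralized: float       # phi
    som_atom_pc: float
    soc_g_kg: float
    covariates: dict[str, dict[str, float]]   # group -> variable -> value

    def control_flux(self, t) -> np.ndarray:
        """SOM-derived control flux, ug C g-1 soil d-1."""
        return two_pool_rate(t, self.twopool) * self.soc_g_kg

    def priming_rate(self, t) -> np.ndarray:
        """True priming rate, ug C g-1 soil d-1."""
        t = np.asarray(t, dtype=float)
        return self.control_flux(t) * self.priming_amplitude * np.exp(
            -self.priming_decay * t
        )

    def glucose_flux(self, t) -> np.ndarray:
        """Glucose-derived flux, ug C g-1 soil d-1."""
        t = np.asarray(t, dtype=float)
        return (
            self.glucose_dose * self.glucose_mineralized * self.glucose_k
            * np.exp(-self.glucose_k * t)
        )

    def cumulative_priming_analytic(self, t_end: float) -> float:
        """Closed-form integral of the priming rate from 0 to t_end."""
        p = self.twopool
        lam = self.priming_decay
        a1 = p.k1 + lam
        a2 = p.k2 + lam
        term1 = p.k1 * p.f1 * (1.0 - np.exp(-a1 * t_end)) / a1
        term2 = p.k2 * (1.0 - p.f1) * (1.0 - np.exp(-a2 * t_end)) / a2
        return float(
            self.soc_g_kg * self.priming_amplitude * p.c_tot * (term1 + term2)
        )


def _loginterp(lo: float, hi: float, u) -> np.ndarray:
    """Map u in [0,1] onto [lo, hi] on a log scale (right-skewed fields)."""
    return lo * (hi / lo) ** np.asarray(u)


def generate_transect(
    n_sites: int = 30,
    seed: int = 0,
    config: TransectConfig = TransectConfig(),
) -> list[SiteTruth]:
    """Draw a transect of sites with correlated covariates and known truth."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    for name in ("precip_range", "npp_range", "soc_range", "mbc_range",
                 "ph_range", "f1_range", "k1_range", "k2_range"):
        lo, hi = getattr(config, name)
        if not lo < hi:
            raise ValueError(f"invalid config range {name}=({lo}, {hi})")
    rng = np.random.default_rng(seed)

    precip = rng.uniform(*config.precip_range, size=n_sites)
    g = (precip - config.precip_range[0]) / np.ptp(config.precip_range)
    g_z = (g - g.mean()) / g.std() if n_sites > 1 else np.zeros(n_sites)

    def u_from(gradient_weight: float) -> np.ndarray:
        eps = rng.normal(size=n_sites)
        return np.clip(gradient_weight * g + (1 - gradient_weight) * 0.5
                       + 0.18 * eps, 0.0, 1.0)

    # --- covariates --------------------------------------------------------
    npp = config.npp_range[0] + np.ptp(config.npp_range) * u_from(0.85)
    anpp = npp * 0.45 * (1 + 0.10 * rng.normal(size=n_sites))
    c_input = npp * 0.22 * (1 + 0.10 * rng.normal(size=n_sites))
    grass = np.clip(55 - 30 * g + 10 * rng.normal(size=n_sites), 5, 90)
    forb = np.clip(15 + 25 * g + 8 * rng.normal(size=n_sites), 2, 80)
    sedge = np.clip(100 - grass - forb + 5 * rng.normal(size=n_sites), 1, 60)

    soc = _loginterp(*config.soc_range, u_from(0.8))
    tn = soc / 10.0 * (1 + 0.15 * rng.normal(size=n_sites))
    ph = config.ph_range[1] - np.ptp(config.ph_range) * u_from(0.8)
    bd = np.clip(1.55 - 0.7 * g + 0.08 * rng.normal(size=n_sites), 0.6, 1.7)
    clay = np.clip(12 + 18 * g + 5 * rng.normal(size=n_sites), 2, 60)

    mbc = _loginterp(*config.mbc_range, u_from(0.8))
    total_plfa = mbc * 0.04 * (1 + 0.2 * rng.normal(size=n_sites))
    fb_ratio = np.clip(0.25 + 0.4 * (1 - g) + 0.08 * rng.normal(size=n_sites),
                       0.05, 1.5)
    c_enzyme = np.exp(1.0 + 0.8 * g + 0.3 * rng.normal(size=n_sites))
    n_enzyme = np.exp(0.6 + 0.7 * g + 0.3 * rng.normal(size=n_sites))

    # SOM stability: latent recalcitrance (tied to gradient) and protection
    recal_lat = 0.5 * g_z + np.sqrt(1 - 0.25) * rng.normal(size=n_sites)
    prot_lat = -0.3 * g_z + np.sqrt(1 - 0.09) * rng.normal(size=n_sites)
    recalcitrant_pool = np.clip(45 + 12 * recal_lat, 5, 85)       # % of SOC
    labile_pool_1 = np.clip(32 - 7 * recal_lat
                            + 3 * rng.normal(size=n_sites), 3, 70)
    labile_pool_2 = np.clip(23 - 5 * recal_lat
                            + 3 * rng.normal(size=n_sites), 3, 60)
    carbohydrates = np.clip(12 - 3 * recal_lat
                            + 1.5 * rng.normal(size=n_sites), 1, 30)
    cutin = np.clip(6 + 2 * recal_lat + rng.normal(size=n_sites), 0.5, 15)
    feal_soc = np.exp(-1.2 + 0.6 * prot_lat)                      # mol mol-1
    ca_soc = np.exp(-0.5 + 0.5 * prot_lat + 0.2 * rng.normal(size=n_sites))
    macroagg_c = np.clip(40 - 8 * prot_lat
                         + 4 * rng.normal(size=n_sites), 5, 80)

    # --- priming signal ----------------------------------------------------
    def z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=0) if n_sites > 1 else np.zeros_like(v)

    pi0 = (
        config.pi0_intercept
        + config.pi0_beta_recalcitrance * z(recalcitrant_pool)
        + config.pi0_beta_protection * z(feal_soc)
        + config.pi0_noise_sd * rng.normal(size=n_sites)
    )
    pi0 = np.clip(pi0, *config.pi0_bounds)
    lam = rng.uniform(*config.priming_decay_range, size=n_sites)

    f1 = rng.uniform(*config.f1_range, size=n_sites)
    k1 = rng.uniform(*config.k1_range, size=n_sites)
    k2 = rng.uniform(*config.k2_range, size=n_sites)

    n_meadow = int(round(config.meadow_fraction * n_sites))
    meadow_idx = set(np.argsort(precip)[n_sites - n_meadow:].tolist())

    truths = []
    for i in range(n_sites):
        covs = {
            "plant": {
                "npp": npp[i], "anpp": anpp[i], "c_input": c_input[i],
                "grass_cover": grass[i], "forb_cover": forb[i],
                "sedge_cover": sedge[i],
            },
            "soil": {
                "soc": soc[i], "tn": tn[i], "ph": ph[i],
                "bulk_density": bd[i], "clay": clay[i],
            },
            "microbial": {
                "mbc": mbc[i], "total_plfa": total_plfa[i],
                "fb_ratio": fb_ratio[i], "c_enzyme": c_enzyme[i],
                "n_enzyme": n_enzyme[i],
            },
            "som_stability": {
                "recalcitrant_pool": recalcitrant_pool[i],
                "labile_pool_1": labile_pool_1[i],
                "labile_pool_2": labile_pool_2[i],
                "carbohydrates": carbohydrates[i],
                "cutin": cutin[i],
                "feal_soc": feal_soc[i],
                "ca_soc": ca_soc[i],
                "macroagg_c": macroagg_c[i],
            },
        }
        truths.append(
            SiteTruth(
                site_id=f"S{i + 1:02d}",
                ecosystem="meadow" if i in meadow_idx else "steppe",
                twopool=TwoPoolParams(f1=float(f1[i]), k1=float(k1[i]),
                                      k2=float(k2[i])),
                priming_amplitude=float(pi0[i]),
                priming_decay=float(lam[i]),
                glucose_dose=float(mbc[i]),   # 100% MBC; mg kg-1 == ug g-1
                glucose_k=config.glucose_k,
                glucose_mineralized=config.glucose_mineralized,
                som_atom_pc=config.som_atom_pc,
                soc_g_kg=float(soc[i]),
                covariates={g_: {k_: float(v_) for k_, v_ in d.items()}
                            for g_, d in covs.items()},
            )
        )
    return truths


def simulate_incubation(
    truth: SiteTruth,
    design: IncubationDesign,
    seed: int = 0,
    flux_noise_rel: float = 0.05,
    atom_pc_noise_abs: float = 0.005,
    blank_conc: float = 0.05,
    constants: Constants = Constants(),
    include_blanks: bool = True,
) -> list[MeasurementRecord]:
    """Noisy measurement records for one site (plus blanks if asked).

    Records carry headspace concentrations and bottle atom% (including
    the blank CO2 contribution), so the reader-side blank correction and
    ideal-gas flux conversion are both exercised.  ``flux_noise_rel`` is
    multiplicative on the respired flux, ``atom_pc_noise_abs`` additive
    on the respired atom%; zero noise makes the pipeline exactly
    invertible.
    """
    if flux_noise_rel < 0 or atom_pc_noise_abs < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[MeasurementRecord] = []

    for day in design.schedule:
        ctl_flux = float(truth.control_flux(day))
        som_treat = ctl_flux * (
            1.0 + truth.priming_amplitude * np.exp(-truth.priming_decay * day)
        )
        gluc = float(truth.glucose_flux(day))
        treat_flux = som_treat + gluc
        at_treat = (
            som_treat * truth.som_atom_pc + gluc * design.glucose_atom_pc
        ) / treat_flux

        for treatment, flux_true, at_true in (
            ("control", ctl_flux, truth.som_atom_pc),
            ("glucose", treat_flux, at_treat),
        ):
            for rep in range(1, design.n_replicates + 1):
                flux = flux_true * (1.0 + flux_noise_rel * rng.normal())
                at = at_true + atom_pc_noise_abs * rng.normal()
                conc_resp = cflux_to_concentration(
                    max(flux, 0.0), design, day=day, constants=constants
                )
                conc = blank_conc + conc_resp
                at_bottle = (
                    (at * conc_resp + constants.blank_atom_pc * blank_conc) / conc
                    if conc > 0 else constants.blank_atom_pc
                )
                records.append(
                    MeasurementRecord(
                        site_id=truth.site_id,
                        bottle_id=f"{truth.site_id}-{treatment[0]}{rep}",
                        treatment=treatment,
                        replicate=rep,
                        day=day,
                        co2_conc=conc,
                        atom_pc=at_bottle,
                    )
                )
        if include_blanks:
            records.extend(
                simulate_blanks(design, day, rng, flux_noise_rel,
                                atom_pc_noise_abs, blank_conc, constants,
                                site_id=truth.site_id)
            )
    return records


def simulate_blanks(
    design: IncubationDesign,
    day: float,
    rng: np.random.Generator,
    flux_noise_rel: float,
    atom_pc_noise_abs: float,
    blank_conc: float,
    constants: Constants,
    site_id: str = "BLANK",
) -> list[MeasurementRecord]:
    """Blank (empty-bottle) records carrying ambient CO2 only."""
    out = []
    for b in range(1, design.n_blanks + 1):
        conc = blank_conc * (1.0 + flux_noise_rel * rng.normal())
        at = constants.blank_atom_pc + atom_pc_noise_abs * rng.normal()
        out.append(
            MeasurementRecord(
                site_id=site_id,
                bottle_id=f"{site_id}-b{b}",
                treatment="blank",
                replicate=b,
                day=day,
                co2_conc=max(conc, 0.0),
                atom_pc=at,
            )
        )
    return out


def simulate_transect(
    truths: list[SiteTruth],
    design: IncubationDesign,
    seed: int = 0,
    flux_noise_rel: float = 0.05,
    atom_pc_noise_abs: float = 0.005,
    blank_conc: float = 0.05,
    constants: Constants = Constants(),
) -> list[MeasurementRecord]:
    """Records for a whole transect with one shared set of blank bottles."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(truths) + 1)
    records: list[MeasurementRecord] = []
    for truth, child in zip(truths, children[:-1]):
        records.extend(
            simulate_incubation(
                truth, design,
                seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
                flux_noise_rel=flux_noise_rel,
                atom_pc_noise_abs=atom_pc_noise_abs,
                blank_conc=blank_conc, constants=constants,
                include_blanks=False,
            )
        )
    blank_rng = np.random.default_rng(children[-1])
    for day in design.schedule:
        records.extend(
            simulate_blanks(design, day, blank_rng, flux_noise_rel,
                            atom_pc_noise_abs, blank_conc, constants)
        )
    return records


def truths_to_covariates(truths: list[SiteTruth]) -> list[SiteCovariates]:
    return [
        SiteCovariates(site_id=t.site_id, group=grp, variable=var, value=val)
        for t in truths
        for grp, block in t.covariates.items()
        for var, val in block.items()
    ]


def truth_frame(truths: list[SiteTruth]) -> pd.DataFrame:
    """Flat per-site truth table (for test assertions and fixtures)."""
    rows = []
    for t in truths:
        rows.append({
            "site_id": t.site_id,
            "ecosystem": t.ecosystem,
            "f1": t.twopool.f1, "k1": t.twopool.k1, "k2": t.twopool.k2,
            "c_tot": t.twopool.c_tot,
            "priming_amplitude": t.priming_amplitude,
            "priming_decay": t.priming_decay,
            "glucose_dose": t.glucose_dose,
            "glucose_k": t.glucose_k,
            "glucose_mineralized": t.glucose_mineralized,
            "som_atom_pc": t.som_atom_pc,
            "soc_g_kg": t.soc_g_kg,
        })
    return pd.DataFrame(rows)


def write_fixtures(
    truths: list[SiteTruth],
    records: list[MeasurementRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit incubation.csv, covariates.csv and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "incubation": out / "incubation.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.csv",
    }
    records_to_frame(records).to_csv(paths["incubation"], index=False)
    pd.DataFrame(
        [(c.site_id, c.group, c.variable, c.value)
         for c in truths_to_covariates(truths)],
        columns=["site_id", "group", "variable", "value"],
    ).to_csv(paths["covariates"], index=False)
    truth_frame(truths).to_csv(paths["truth"], index=False)
    return paths
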