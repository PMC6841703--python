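"""Isotope source partitioning and priming-effect quantification.

The chain is: blank-correct the measured CO2 isotope composition, split
respiration between glucose-derived and SOM-derived C by two-endmember
mixing in atom% 13C space, difference the SOM-derived flux under
treatment against the control to get the priming effect, and integrate
over the incubation for the cumulative value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    Constants,
    IncubationDesign,
    MeasurementRecord,
    PartitionError,
    concentration_to_cflux,
)

logger = logging.getLogger(__name__)

#: two endmembers closer than this (atom%) cannot be partitioned
ENDMEMBER_TOLERANCE = 1e-6


@dataclass
class PartitionPoint:
    """Source split of treated-soil respiration at one site x day."""

    site_id: str
    day: float
    f_glucose: float
    f_som: float
    c_treat: float          # ug CO2-C g-1 d-1, treated soil total
    c_control: float        # ug CO2-C g-1 d-1, control soil
    som_flux_treat: float   # c_treat * f_som
    clamped: bool = False


@dataclass
class PrimingPoint:
    """Priming effect at one site x day; negative values preserved."""

    site_id: str
    day: float
    priming: float              # ug CO2-C g-1 d-1
    relative_priming: float | None   # % of basal (control) respiration


def blank_correct_atom_pc(
    at_soil: float, c_soil: float, at_blank: float, c_blank: float
) -> float:
    """Remove the blank (ambient headspace) CO2 contribution.

    Returns (at_soil*c_soil - at_blank*c_blank) / (c_soil - c_blank):
    the isotope composition of the respired CO2 alone, given bottle and
    blank concentrations in the same units.
    """
    if c_blank < 0:
        raise PartitionError("blank concentration must be >= 0")
    if c_blank == 0:
        return at_soil
    if c_soil <= c_blank:
        raise PartitionError(
            f"bottle CO2 ({c_soil:g}) does not exceed blank ({c_blank:g}); "
            "respired CO2 isotope composition is undefined"
        )
    return (at_soil * c_soil - at_blank * c_blank) / (c_soil - c_blank)


def partition_source(
    at_treat: float,
    at_som: float,
    at_glucose: float,
    clamp: bool = True,
) -> tuple[float, float, bool]:
    """Two-endmember mixing split of treated respiration.

    f_glucose = (at_treat - at_som) / (at_glucose - at_som) and
    f_som = 1 - f_glucose.  Fractions falling outside [0, 1] through
    measurement noise are clamped (flagged) unless ``clamp=False``.

    Returns ``(f_glucose, f_som, clamped)``.
    """
    if abs(at_glucose - at_som) < ENDMEMBER_TOLERANCE:
        raise PartitionError(
            "glucose and SOM endmembers are isotopically indistinguishable "
            f"({at_glucose:g} vs {at_som:g} atom%)"
        )
    f_glucose = (at_treat - at_som) / (at_glucose - at_som)
    clamped = False
    if clamp and not 0.0 <= f_glucose <= 1.0:
        logger.warning(
            "glucose fraction %.4f outside [0, 1]; clamping", f_glucose
        )
        f_glucose = min(max(f_glucose, 0.0), 1.0)
        clamped = True
    return f_glucose, 1.0 - f_glucose, clamped


def priming_effect(
    c_treat: float,
    f_som: float,
    c_control: float,
    site_id: str = "",
    day: float = np.nan,
) -> PrimingPoint:
    """Priming = SOM-derived flux under treatment minus control flux.

    Relative priming is expressed in % of basal respiration; it is
    undefined (None, with a warning) when the control flux is not
    positive.  Negative priming (suppression) is preserved.
    """
    priming = c_treat * f_som - c_control
    if c_control > 0:
        relative = 100.0 * priming / c_control
    else:
        logger.warning(
            "control flux %.4g <= 0 at site %s day %s; "
            "relative priming undefined", c_control, site_id, day,
        )
        relative = None
    return PrimingPoint(site_id=site_id, day=day, priming=priming,
                        relative_priming=relative)


def cumulative_priming(
    days: np.ndarray,
    rates: np.ndarray,
    include_day0_rectangle: bool = True,
) -> float:
    """Integrate a per-day priming-rate series to cumulative ug C g-1.

    Trapezoidal rule across the measured days; optionally a leading
    rectangle from day 0 to the first measured day at the first rate, so
    the cumulative value spans the full incubation window.
    """
    days = np.asarray(days, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if days.size == 0:
        raise ValueError("need at least one (day, rate) point")
    if days.size != rates.size:
        raise ValueError("days and rates must have equal length")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    total = float(np.trapezoid(rates, days))
    if include_day0_rectangle and days[0] > 0:
        total += float(days[0] * rates[0])
    return total


def aggregate_replicates(
    records: list[MeasurementRecord],
    design: IncubationDesign,
    constants: Constants = Constants(),
) -> pd.DataFrame:
    """Collapse bottles to per-(site, treatment, day) mean and SD.

    Concentration-bearing records are blank-corrected (isotopes) and
    converted to fluxes first, using the blank bottles of the same day.
    Returns a frame indexed by (site_id, treatment, day) with columns
    flux_mean, flux_sd, atom_pc_mean, atom_pc_sd, n.  SD is NaN for
    single replicates.
    """
    blanks = [r for r in records if r.treatment == "blank"]
    blank_by_day: dict[float, tuple[float, float]] = {}
    for day in sorted({r.day for r in blanks}):
        sub = [r for r in blanks if r.day == day]
        conc = float(np.mean([r.co2_conc for r in sub if r.co2_conc is not None]))
        ats = [r.atom_pc for r in sub if r.atom_pc is not None]
        at = float(np.mean(ats)) if ats else constants.blank_atom_pc
        blank_by_day[day] = (conc, at)

    rows = []
    for r in records:
        if r.treatment == "blank":
            continue
        if r.co2_conc is not None:
            c_blank, at_blank = blank_by_day.get(r.day, (0.0, constants.blank_atom_pc))
            flux = concentration_to_cflux(
                r.co2_conc, c_blank, design, day=r.day, constants=constants
            )
            atom_pc = (
                blank_correct_atom_pc(r.atom_pc, r.co2_conc, at_blank, c_blank)
                if r.atom_pc is not None
                else None
            )
        else:
            flux, atom_pc = r.flux, r.atom_pc
        rows.append(
            (r.site_id, r.treatment, r.day, r.replicate, flux, atom_pc)
        )
    df = pd.DataFrame(
        rows, columns=["site_id", "treatment", "day", "replicate", "flux", "atom_pc"]
    )
    if df.empty:
        raise PartitionError("no non-blank records to aggregate")

    grouped = df.groupby(["site_id", "treatment", "day"])
    agg = grouped.agg(
        flux_mean=("flux", "mean"),
        flux_sd=("flux", lambda x: x.std(ddof=1)),
        atom_pc_mean=("atom_pc", "mean"),
        atom_pc_sd=("atom_pc", lambda x: x.std(ddof=1)),
        n=("flux", "size"),
    )
    return agg


def partition_sites(
    records: list[MeasurementRecord],
    design: IncubationDesign,
    constants: Constants = Constants(),
    at_som_override: dict[str, float] | None = None,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Run the full partitioning chain over an incubation table.

    Replicates are aggregated first (means feed the mixing equations);
    the SOM endmember defaults to the blank-corrected control-soil
    respiration atom% of the same site and day, overridable per site via
    ``at_som_override``.  With ``per_replicate=True`` an additional
    per-replicate glucose-treatment partition is computed (diagnostics
    and error propagation) and the per-cell SD of f_som is reported.

    Returns one row per site x day: fractions, fluxes, priming,
    relative priming, clamp flag, plus replicate SDs needed downstream.
    """
    agg = aggregate_replicates(records, design, constants)
    # per-replicate treated fluxes/atom% for f_som spread (diagnostics + Eq. 6 input)
    rep_fsom_sd: dict[tuple[str, float], float] = {}
    if per_replicate:
        rep_fsom_sd = _per_replicate_fsom_sd(
            records, design, constants, agg, at_som_override
        )

    out_rows = []
    sites = sorted({idx[0] for idx in agg.index})
    for site in sites:
        try:
            ctl = agg.loc[(site, "control")]
            trt = agg.loc[(site, "glucose")]
        except KeyError as exc:
            raise PartitionError(
                f"site {site}: missing treatment cell {exc}"
            ) from exc
        for day in sorted(set(ctl.index) & set(trt.index)):
            c_control = float(ctl.loc[day, "flux_mean"])
            c_treat = float(trt.loc[day, "flux_mean"])
            at_treat = float(trt.loc[day, "atom_pc_mean"])
            if at_som_override and site in at_som_override:
                at_som = at_som_override[site]
            else:
                at_som = float(ctl.loc[day, "atom_pc_mean"])
            f_glucose, f_som, clamped = partition_source(
                at_treat, at_som, design.glucose_atom_pc
            )
            pp = priming_effect(c_treat, f_som, c_control, site_id=site, day=day)
            out_rows.append({
                "site_id": site,
                "day": day,
                "f_glucose": f_glucose,
                "f_som": f_som,
                "c_treat": c_treat,
                "c_control": c_control,
                "som_flux_treat": c_treat * f_som,
                "priming": pp.priming,
                "relative_priming": pp.relative_priming,
                "clamped": clamped,
                "c_treat_sd": float(trt.loc[day, "flux_sd"]),
                "c_control_sd": float(ctl.loc[day, "flux_sd"]),
                "f_som_sd": rep_fsom_sd.get((site, day), np.nan),
                "n_treat": int(trt.loc[day, "n"]),
                "n_control": int(ctl.loc[day, "n"]),
            })
    return pd.DataFrame(out_rows)


def _per_replicate_fsom_sd(records, design, constants, agg, at_som_override):
    """SD of f_som across glucose-treatment replicates, per site x day."""
    blanks = [r for r in records if r.treatment == "blank"]
    blank_by_day = {}
    for day in sorted({r.day for r in blanks}):
        sub = [r for r in blanks if r.day == day]
        conc = float(np.mean([r.co2_conc for r in sub if r.co2_conc is not None]))
        ats = [r.atom_pc for r in sub if r.atom_pc is not None]
        at = float(np.mean(ats)) if ats else constants.blank_atom_pc
        blank_by_day[day] = (conc, at)

    per_cell: dict[tuple[str, float], list[float]] = {}
    for r in records:
        if r.treatment != "glucose" or r.atom_pc is None:
            continue
        if r.co2_conc is not None:
            c_blank, at_blank = blank_by_day.get(r.day, (0.0, constants.blank_atom_pc))
            at_treat = blank_correct_atom_pc(r.atom_pc, r.co2_conc, at_blank, c_blank)
        else:
            at_treat = r.atom_pc
        if at_som_override and r.site_id in at_som_override:
            at_som = at_som_override[r.site_id]
        else:
            try:
                at_som = float(
                    agg.loc[(r.site_id, "control", r.day), "atom_pc_mean"]
                )
            except KeyError:
                continue
        _, f_som, _ = partition_source(at_treat, at_som, design.glucose_atom_pc)
        per_cell.setdefault((r.site_id, r.day), []).append(f_som)
    return {
        k: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
        for k, v in per_cell.items()
    }


def cumulative_by_site(
    partition: pd.DataFrame,
    design: IncubationDesign,
) -> pd.DataFrame:
    """Cumulative priming (and respiration) per site from a partition table."""
    rows = []
    for site, sub in partition.groupby("site_id"):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy()
        rows.append({
            "site_id": site,
            "cumulative_priming": cumulative_priming(
                days, sub["priming"].to_numpy(), design.include_day0_rectangle
            ),
            "cumulative_control": cumulative_priming(
                days, sub["c_control"].to_numpy(), design.include_day0_rectangle
            ),
            "cumulative_treat": cumulative_priming(
                days, sub["c_treat"].to_numpy(), design.include_day0_rectangle
            ),
        })
    df = pd.DataFrame(rows)
    df["cumulative_relative_priming"] = (
        100.0 * df["cumulative_priming"] / df["cumulative_control"]
    )
    return df
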