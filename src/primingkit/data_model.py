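"""Domain types, table schemas, unit conversions and validation.

All downstream computation operates on CO2-C mass fluxes (ug CO2-C per g
dry soil per day) and absolute isotope abundance (atom% 13C).  Headspace
concentrations (mmol CO2 mol-1) and delta-13C values (permil vs VPDB) are
converted at ingest and never downstream.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 13C/12C isotope ratio of the VPDB standard.  0.011237 is also in use;
#: override through ``Constants.r_vpdb`` if matching older literature.
R_VPDB_DEFAULT = 0.0111802

#: atom% 13C assigned to blank-bottle CO2 when not measured (close to
#: natural abundance, -8 permil vs VPDB is ~1.097 atom%).
BLANK_ATOM_PC_DEFAULT = 1.08

TREATMENTS = ("control", "glucose", "blank")

MOLAR_MASS_C = 12.011       # g mol-1
R_GAS = 8.31446261815324    # J mol-1 K-1
ATM_PA = 101325.0           # Pa


class SchemaError(ValueError):
    """A table row violates the incubation schema."""


class PartitionError(ValueError):
    """Isotope partitioning is impossible for the given inputs."""


@dataclass(frozen=True)
class Constants:
    """Physical and calibration constants shared across the pipeline."""

    r_vpdb: float = R_VPDB_DEFAULT
    blank_atom_pc: float = BLANK_ATOM_PC_DEFAULT
    pressure_pa: float = ATM_PA


@dataclass(frozen=True)
class IncubationDesign:
    """Layout of the incubation experiment.

    Defaults follow the transect study design: measurements on days
    1, 3, 8, 15, 35 and 65 at 15 degC, glucose labelled at 3.0 atom% 13C
    dosed at 100% of microbial biomass C, triplicate bottles plus five
    blanks.  ``accumulation_hours`` may be a single value or one value
    per scheduled day (gas accumulates 2 h early on, 8 h once fluxes
    decline).
    """

    schedule: tuple[float, ...] = (1.0, 3.0, 8.0, 15.0, 35.0, 65.0)
    temperature_c: float = 15.0
    soil_mass_g: float = 20.0
    headspace_volume_l: float = 0.25
    glucose_atom_pc: float = 3.0
    glucose_dose_rule: float = 1.0   # fraction of microbial biomass C
    accumulation_hours: tuple[float, ...] = (2.0, 2.0, 2.0, 8.0, 8.0, 8.0)
    n_replicates: int = 3
    n_blanks: int = 5
    include_day0_rectangle: bool = True

    def __post_init__(self) -> None:
        sched = tuple(float(d) for d in self.schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must be strictly increasing")
        if not 1.0 < self.glucose_atom_pc < 100.0:
            raise ValueError("glucose_atom_pc must lie in (1, 100)")
        acc = self.accumulation_hours
        if np.isscalar(acc):
            acc = (float(acc),) * len(sched)
        else:
            acc = tuple(float(a) for a in acc)
            if len(acc) == 1:
                acc = acc * len(sched)
            elif len(acc) != len(sched):
                raise ValueError(
                    "accumulation_hours must be scalar or one per scheduled day"
                )
        if any(a <= 0 for a in acc):
            raise ValueError("accumulation_hours must be positive")
        object.__setattr__(self, "schedule", sched)
        object.__setattr__(self, "accumulation_hours", acc)

    def accumulation_hours_for(self, day: float) -> float:
        """Gas accumulation window for a scheduled day (nearest match)."""
        idx = int(np.argmin([abs(day - d) for d in self.schedule]))
        return self.accumulation_hours[idx]

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15


@dataclass
class MeasurementRecord:
    """One bottle x timepoint observation.

    Exactly one of ``co2_conc`` (mmol CO2 mol-1 headspace) or ``flux``
    (ug CO2-C g-1 d-1, already blank-corrected) must be present, and at
    most one of ``atom_pc`` / ``delta13c`` for the isotope composition.
    """

    site_id: str
    bottle_id: str
    treatment: str
    replicate: int
    day: float
    co2_conc: float | None = None
    flux: float | None = None
    atom_pc: float | None = None
    delta13c: float | None = None
    row: int | None = None   # source row, for error messages

    def __post_init__(self) -> None:
        where = f" (row {self.row})" if self.row is not None else ""
        if self.treatment not in TREATMENTS:
            raise SchemaError(
                f"unknown treatment {self.treatment!r}{where}; "
                f"expected one of {TREATMENTS}"
            )
        if self.day < 0:
            raise SchemaError(f"day must be >= 0{where}")
        if self.co2_conc is None and self.flux is None:
            raise SchemaError(
                f"record needs co2_conc or flux{where}"
            )
        if self.co2_conc is not None and self.co2_conc < 0:
            raise SchemaError(f"co2_conc must be >= 0{where}")
        if self.atom_pc is not None and self.delta13c is not None:
            raise SchemaError(
                f"give atom_pc or delta13c, not both{where}"
            )
        if self.atom_pc is not None and not 0.0 < self.atom_pc < 100.0:
            raise SchemaError(f"atom_pc must lie in (0, 100){where}")
        if self.replicate < 1:
            raise SchemaError(f"replicate must be >= 1{where}")


@dataclass(frozen=True)
class SiteCovariates:
    """One covariate value for one site, tagged by variable group."""

    site_id: str
    group: str
    variable: str
    value: float

    GROUPS = ("plant", "soil", "microbial", "som_stability")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise SchemaError(
                f"unknown covariate group {self.group!r}; expected {self.GROUPS}"
            )


# ---------------------------------------------------------------------------
# unit conversions

def delta_to_atom_percent(delta: float, r_vpdb: float = R_VPDB_DEFAULT):
    """Convert delta-13C (permil vs VPDB) to absolute abundance (atom% 13C).

    atom% = 100 R / (1 + R) with R = R_VPDB (delta/1000 + 1).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta13c must exceed -1000 permil")
    r = r_vpdb * (delta / 1000.0 + 1.0)
    out = 100.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def atom_percent_to_delta(atom_pc: float, r_vpdb: float = R_VPDB_DEFAULT):
    """Inverse of :func:`delta_to_atom_percent`."""
    atom_pc = np.asarray(atom_pc, dtype=float)
    if np.any((atom_pc <= 0.0) | (atom_pc >= 100.0)):
        raise ValueError("atom_pc must lie in (0, 100)")
    r = atom_pc / (100.0 - atom_pc)
    out = 1000.0 * (r / r_vpdb - 1.0)
    return float(out) if out.ndim == 0 else out


def concentration_to_cflux(
    conc_soil: float,
    conc_blank: float,
    design: IncubationDesign,
    day: float | None = None,
    constants: Constants = Constants(),
    negative_tolerance: float = 1e-9,
) -> float:
    """Net headspace CO2 accumulation -> CO2-C mass flux.

    Converts the net concentration (soil bottle minus blank, mmol CO2
    mol-1 air) to moles of CO2 via the ideal gas law at the incubation
    temperature and 1 atm, then to ug C per g dry soil per day using the
    accumulation window for ``day``.
    """
    net = conc_soil - conc_blank
    if net < -negative_tolerance:
        raise PartitionError(
            f"soil-bottle CO2 ({conc_soil:g}) below blank ({conc_blank:g}); "
            "cannot form a non-negative flux"
        )
    net = max(net, 0.0)
    hours = (
        design.accumulation_hours_for(day)
        if day is not None
        else design.accumulation_hours[0]
    )
    n_air = constants.pressure_pa * (design.headspace_volume_l * 1e-3) / (
        R_GAS * design.temperature_k
    )
    mol_co2 = net * 1e-3 * n_air
    ug_c = mol_co2 * MOLAR_MASS_C * 1e6
    return ug_c / design.soil_mass_g / (hours / 24.0)


def cflux_to_concentration(
    flux: float,
    design: IncubationDesign,
    day: float | None = None,
    constants: Constants = Constants(),
) -> float:
    """Inverse of :func:`concentration_to_cflux` for a zero blank."""
    hours = (
        design.accumulation_hours_for(day)
        if day is not None
        else design.accumulation_hours[0]
    )
    n_air = constants.pressure_pa * (design.headspace_volume_l * 1e-3) / (
        R_GAS * design.temperature_k
    )
    ug_c = flux * design.soil_mass_g * (hours / 24.0)
    mol_co2 = ug_c / (MOLAR_MASS_C * 1e6)
    return mol_co2 / n_air * 1e3


# ---------------------------------------------------------------------------
# tabular IO

INCUBATION_COLUMNS = (
    "site_id", "bottle_id", "treatment", "replicate", "day",
    "co2_conc_mmol_mol", "flux_ugC_g_d", "atom_pc", "delta13c_permil",
)

COVARIATE_COLUMNS = ("site_id", "group", "variable", "value")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_incubation_table(
    path: str | Path,
    design: IncubationDesign | None = None,
    constants: Constants = Constants(),
) -> list[MeasurementRecord]:
    """Read and validate an incubation CSV (see ``INCUBATION_COLUMNS``).

    delta-13C columns are converted to atom% at ingest.  Raises
    :class:`SchemaError` naming the offending row for unknown treatments,
    duplicate (bottle, day) pairs or rows carrying neither a
    concentration nor a flux.
    """
    df = pd.read_csv(path)
    missing = set(INCUBATION_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise SchemaError(f"incubation table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("incubation table %s contains no data rows", path)
        return []
    records: list[MeasurementRecord] = []
    seen: set[tuple[str, float]] = set()
    for i, r in df.iterrows():
        row = int(i) + 2   # header is line 1
        key = (str(r["bottle_id"]), float(r["day"]))
        if key in seen:
            raise SchemaError(f"duplicate bottle/day {key} (row {row})")
        seen.add(key)
        atom_pc = _opt(r.get("atom_pc"))
        delta = _opt(r.get("delta13c_permil"))
        if atom_pc is None and delta is not None:
            atom_pc = delta_to_atom_percent(delta, constants.r_vpdb)
            delta = None
        records.append(
            MeasurementRecord(
                site_id=str(r["site_id"]),
                bottle_id=str(r["bottle_id"]),
                treatment=str(r["treatment"]),
                replicate=int(r["replicate"]),
                day=float(r["day"]),
                co2_conc=_opt(r.get("co2_conc_mmol_mol")),
                flux=_opt(r.get("flux_ugC_g_d")),
                atom_pc=atom_pc,
                delta13c=delta,
                row=row,
            )
        )
    return records


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Serialize records into the canonical incubation table layout."""
    rows = [
        {
            "site_id": r.site_id,
            "bottle_id": r.bottle_id,
            "treatment": r.treatment,
            "replicate": r.replicate,
            "day": r.day,
            "co2_conc_mmol_mol": r.co2_conc,
            "flux_ugC_g_d": r.flux,
            "atom_pc": r.atom_pc,
            "delta13c_permil": r.delta13c,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(INCUBATION_COLUMNS))


def read_covariates_table(path: str | Path) -> list[SiteCovariates]:
    """Read the long-format site covariate CSV."""
    df = pd.read_csv(path)
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"covariate table missing columns: {sorted(missing)}")
    out: list[SiteCovariates] = []
    seen: set[tuple[str, str, str]] = set()
    for i, r in df.iterrows():
        key = (str(r["site_id"]), str(r["group"]), str(r["variable"]))
        if key in seen:
            raise SchemaError(f"duplicate covariate entry {key} (row {int(i) + 2})")
        seen.add(key)
        out.append(
            SiteCovariates(
                site_id=key[0], group=key[1], variable=key[2],
                value=float(r["value"]),
            )
        )
    return out


def covariates_to_wide(covs: Sequence[SiteCovariates]) -> pd.DataFrame:
    """Pivot long covariates to a site x variable matrix.

    Columns get a MultiIndex (group, variable) so group blocks can be
    selected directly.
    """
    df = pd.DataFrame(
        [(c.site_id, c.group, c.variable, c.value) for c in covs],
        columns=list(COVARIATE_COLUMNS),
    )
    wide = df.pivot_table(
        index="site_id", columns=["group", "variable"], values="value"
    )
    return wide.sort_index()


# ---------------------------------------------------------------------------
# configuration

def load_config(path: str | Path) -> tuple[IncubationDesign, Constants]:
    """Load ``[design]`` and ``[constants]`` sections from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    d = raw.get("design", {})
    design = IncubationDesign(
        schedule=tuple(d.get("schedule", IncubationDesign.schedule)),
        temperature_c=d.get("temperature_c", IncubationDesign.temperature_c),
        soil_mass_g=d.get("soil_mass_g", IncubationDesign.soil_mass_g),
        headspace_volume_l=d.get(
            "headspace_volume_l", IncubationDesign.headspace_volume_l
        ),
        glucose_atom_pc=d.get("glucose_atom_pc", IncubationDesign.glucose_atom_pc),
        glucose_dose_rule=d.get(
            "glucose_dose_rule", IncubationDesign.glucose_dose_rule
        ),
        accumulation_hours=tuple(np.atleast_1d(
            d.get("accumulation_hours", IncubationDesign.accumulation_hours)
        )),
        n_replicates=d.get("n_replicates", IncubationDesign.n_replicates),
        n_blanks=d.get("n_blanks", IncubationDesign.n_blanks),
        include_day0_rectangle=d.get(
            "include_day0_rectangle", IncubationDesign.include_day0_rectangle
        ),
    )
    c = raw.get("constants", {})
    constants = Constants(
        r_vpdb=c.get("r_vpdb", R_VPDB_DEFAULT),
        blank_atom_pc=c.get("blank_atom_pc", BLANK_ATOM_PC_DEFAULT),
        pressure_pa=c.get("pressure_pa", ATM_PA),
    )
    return design, constants
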