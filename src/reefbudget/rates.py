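"""Derived quantities from incubation experiments.

Converts raw bottle/chamber tables into the rates the budget model consumes:
cell-specific DOC and O2 demands from dark incubations, area-normalized
dissolved and gaseous O2 production from sealed producer chambers, gas
fractions, biomass changes, and open-tank ebullition rates.

Internally SI-friendly: moles via the ideal gas law in Pa/m^3/K, with thin
conversions from the display units the tables carry (µmol L^-1, mL, cm^2,
days).  Table functions take the pandas DataFrames produced by
:mod:`reefbudget.synthetic` (or equivalently-shaped CSVs) and append derived
columns; scalar cores are exposed for direct use and for oracle testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

R_GAS = 8.314  # J K^-1 mol^-1

__all__ = [
    "BiomassCoefficients",
    "cell_specific_demand",
    "cell_specific_demands",
    "cell_volume",
    "biomass_from_volume",
    "biomass_change_per_area",
    "pop_dissolved_production_rate",
    "pop_gas_moles_umol",
    "pop_gas_production_rate",
    "gas_fraction",
    "pop_rates",
    "open_tank_rate",
    "open_tank_rates",
    "summarize",
]


@dataclass(frozen=True)
class BiomassCoefficients:
    """Allometric volume-to-mass conversion, mass = scale * V^exponent (fg).

    Default is a literature dry-mass relationship for marine bacterioplankton
    (scale 435 fg µm^-3^0.86); both numbers are configuration, not results.
    """

    scale: float = 435.0
    exponent: float = 0.86

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be strictly positive")


# ---------------------------------------------------------------------------
# dark incubations: cell-specific demands

def cell_specific_demand(start, end, cells_start, cells_end):
    """Consumption of a dissolved quantity per newly produced cell.

    (start - end) / (cells_end - cells_start); concentrations in µmol L^-1,
    abundances in cells L^-1, so the result is µmol cell^-1.  Positive when
    the quantity was consumed.  A non-positive cell yield makes the demand
    undefined: NaN is returned (flagged, never raised) so such bottles can be
    excluded from summaries.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    yield_ = np.asarray(cells_end, dtype=float) - np.asarray(cells_start, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(yield_ > 0, (start - end) / yield_, np.nan)
    return float(out) if out.ndim == 0 else out


def cell_specific_demands(dark: pd.DataFrame) -> pd.DataFrame:
    """Append DOC_demand / O2_demand (µmol cell^-1) and a validity flag."""
    out = dark.copy()
    out["DOC_demand"] = cell_specific_demand(
        dark["DOC_start"], dark["DOC_end"], dark["cells_start"], dark["cells_end"]
    )
    out["O2_demand"] = cell_specific_demand(
        dark["O2_start"], dark["O2_end"], dark["cells_start"], dark["cells_end"]
    )
    out["demand_defined"] = (dark["cells_end"] - dark["cells_start"]) > 0
    return out


# ---------------------------------------------------------------------------
# cell geometry and biomass

def cell_volume(length_um, width_um):
    """Volume of a cell modeled as a cylinder with hemispherical caps, µm^3.

    V = (pi/4) w^2 (l - w/3), with l the cap-to-cap length; l = w is a
    sphere (pi w^3 / 6).
    """
    length = np.asarray(length_um, dtype=float)
    width = np.asarray(width_um, dtype=float)
    if np.any(width <= 0) or np.any(length < width):
        raise ValueError("need length >= width > 0")
    out = (math.pi / 4.0) * width**2 * (length - width / 3.0)
    return float(out) if out.ndim == 0 else out


def biomass_from_volume(volume_um3, coeffs: BiomassCoefficients = BiomassCoefficients()):
    """Per-cell mass in fg from the allometric power law scale * V^exponent."""
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    out = coeffs.scale * v**coeffs.exponent
    return float(out) if out.ndim == 0 else out


def biomass_change_per_area(
    start_abundance,
    start_mean_volume,
    end_abundance,
    end_mean_volume,
    bottle_volume_l,
    area_cm2,
    coeffs: BiomassCoefficients = BiomassCoefficients(),
):
    """Change in total microbial biomass per producer area, fg cm^-2.

    Abundances in cells L^-1, mean cell volumes in µm^3.  The sign is
    preserved: producers whose exudates shrink the community give negative
    changes.  Controls have no producer area and are reported unnormalized
    (pass area_cm2=None -> fg L^-1, i.e. the concentration change).
    """
    for v in (start_abundance, start_mean_volume, end_abundance, end_mean_volume):
        if v is None or (np.ndim(v) == 0 and not np.isfinite(v)):
            raise ValueError("missing biomass endpoint")
    start_conc = np.asarray(start_abundance, dtype=float) * biomass_from_volume(
        start_mean_volume, coeffs
    )
    end_conc = np.asarray(end_abundance, dtype=float) * biomass_from_volume(
        end_mean_volume, coeffs
    )
    delta_conc = end_conc - start_conc  # fg L^-1
    if area_cm2 is None:
        return delta_conc if delta_conc.ndim else float(delta_conc)
    area = np.asarray(area_cm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be strictly positive")
    out = delta_conc * np.asarray(bottle_volume_l, dtype=float) / area
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# POP chambers: dissolved and gaseous production

def pop_dissolved_production_rate(
    o2_start, o2_end, chamber_volume_l, surface_area_cm2, duration_days
):
    """Net dissolved O2 production, µmol cm^-2 day^-1.

    (end - start concentration) * chamber volume, spread over organism
    surface area and elapsed days.
    """
    area = np.asarray(surface_area_cm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("surface area must be strictly positive")
    delta = np.asarray(o2_end, dtype=float) - np.asarray(o2_start, dtype=float)
    out = delta * np.asarray(chamber_volume_l, dtype=float) / (
        area * np.asarray(duration_days, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


def pop_gas_moles_umol(gas_volume_ml, gas_o2_fraction, pressure_pa=101325.0, temperature_k=298.15):
    """Headspace O2 in µmol via the ideal gas law, n = p V f / (R T).

    The pooled headspace is taken at external pressure: once bubbles
    coalesce at the top of the chamber their curvature over-pressure is
    released.
    """
    f = np.asarray(gas_o2_fraction, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("gas O2 fraction must lie in [0, 1]")
    v_m3 = np.asarray(gas_volume_ml, dtype=float) * 1e-6
    if np.any(v_m3 < 0):
        raise ValueError("gas volume must be non-negative")
    n_mol = np.asarray(pressure_pa, dtype=float) * v_m3 * f / (R_GAS * np.asarray(temperature_k, dtype=float))
    out = n_mol * 1e6
    return float(out) if out.ndim == 0 else out


def pop_gas_production_rate(
    gas_volume_ml, gas_o2_fraction, surface_area_cm2, duration_days,
    pressure_pa=101325.0, temperature_k=298.15,
):
    """Gaseous O2 production, µmol cm^-2 day^-1."""
    n_umol = pop_gas_moles_umol(gas_volume_ml, gas_o2_fraction, pressure_pa, temperature_k)
    area = np.asarray(surface_area_cm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("surface area must be strictly positive")
    out = np.asarray(n_umol) / (area * np.asarray(duration_days, dtype=float))
    return float(out) if out.ndim == 0 else out


def gas_fraction(gas_rate, net_dissolved_rate):
    """Fraction of total photosynthetic O2 released as gas.

    gas / (gas + net dissolved); NaN (flagged-undefined) when the total is
    not positive.
    """
    g = np.asarray(gas_rate, dtype=float)
    total = g + np.asarray(net_dissolved_rate, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, g / total, np.nan)
    return float(out) if out.ndim == 0 else out


def pop_rates(pop: pd.DataFrame) -> pd.DataFrame:
    """Per-bottle rates for non-control POP records.

    Appends ``net_dissolved_rate``, ``gas_rate``, ``gas_moles_umol`` and
    ``gas_frac``; the probe lower-bound flag is carried through so that
    flagged bottles stay identifiable in every derived column.
    """
    rec = pop[pop["group"] != "control"].copy()
    rec["net_dissolved_rate"] = pop_dissolved_production_rate(
        rec["O2_diss_start"], rec["O2_diss_end"], rec["chamber_volume"],
        rec["surface_area"], rec["duration_days"],
    )
    rec["gas_moles_umol"] = pop_gas_moles_umol(
        rec["gas_volume"], rec["gas_O2_fraction"],
        rec["external_pressure"], rec["temperature"],
    )
    rec["gas_rate"] = rec["gas_moles_umol"] / (rec["surface_area"] * rec["duration_days"])
    rec["gas_frac"] = gas_fraction(rec["gas_rate"], rec["net_dissolved_rate"])
    return rec


# ---------------------------------------------------------------------------
# open-tank ebullition

def open_tank_rate(total_bubbles, minutes, area_dm2):
    """Area-normalized ebullition rate, bubbles min^-1 dm^-2."""
    mins = np.asarray(minutes, dtype=float)
    area = np.asarray(area_dm2, dtype=float)
    if np.any(mins <= 0) or np.any(area <= 0):
        raise ValueError("minutes and area must be strictly positive")
    out = np.asarray(total_bubbles, dtype=float) / mins / area
    return float(out) if out.ndim == 0 else out


def open_tank_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-minute bubble counts to one rate per treatment/replicate."""
    grouped = counts.groupby(["treatment", "group", "replicate"], sort=False).agg(
        total_bubbles=("count", "sum"),
        minutes=("minute", "size"),
        surface_area_dm2=("surface_area_dm2", "first"),
    )
    grouped = grouped.reset_index()
    grouped["rate"] = open_tank_rate(
        grouped["total_bubbles"], grouped["minutes"], grouped["surface_area_dm2"]
    )
    return grouped


# ---------------------------------------------------------------------------
# summaries

def summarize(df: pd.DataFrame, value_cols, by=("treatment", "group")) -> pd.DataFrame:
    """Mean, SE and n per group for the given value columns.

    NaN entries (flagged-undefined results) are excluded column-wise, so a
    bottle with an undefined demand drops out of that summary only.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    rows = []
    for keys, sub in df.groupby(list(by), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            n = vals.size
            row[f"{col}_mean"] = vals.mean() if n else np.nan
            row[f"{col}_se"] = vals.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan
            row[f"{col}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)
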