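"""Synthetic experiment tables with the statistical structure of the real
incubation designs.

Four generators emulate the endpoint statistics of the four experiments the
analysis consumes: dark bottle incubations (DOC, O2, cell abundances),
sealed producer chambers with a gas headspace, open-tank bubble counting,
and microscopy cell-size measurements.  Only endpoint statistics are
emulated — no mechanistic growth or photosynthesis dynamics.

Noise families: Gaussian (truncated at physical bounds by resampling) for
continuous endpoint measurements, Poisson for bubble counts, log-normal for
bubble diameters and cell volumes.  Every table is reproducible: one
pseudorandom stream per (design seed, experiment kind, treatment label), so
adding a treatment never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentSpec",
    "ExperimentDesign",
    "generate_dark_incubation",
    "generate_pop_experiment",
    "generate_open_tank",
    "generate_cell_sizes",
    "default_dark_design",
    "default_pop_design",
    "default_open_tank_design",
    "default_cell_size_design",
    "save_table",
]

GROUPS = ("calcifying", "fleshy", "control")
KINDS = ("dark_incubation", "pop_chamber", "open_tank", "cell_sizes")

# Quantities each experiment kind understands (required / optional).
_QUANTITIES = {
    "dark_incubation": (
        {"DOC_start", "DOC_end", "O2_start", "O2_end", "cells_start", "cells_end"},
        set(),
    ),
    "pop_chamber": (
        {"O2_diss_start", "O2_diss_end", "gas_volume", "gas_O2_fraction"},
        {"surface_area", "cells_end"},
    ),
    "open_tank": (
        {"bubbles_per_min_per_dm2", "bubble_diameter_mean", "bubble_diameter_sd",
         "surface_area_dm2", "duration_min"},
        {"PAR", "n_bubbles_measured"},
    ),
    "cell_sizes": (
        {"volume_median", "aspect_mean"},
        {"volume_sigma_log", "aspect_sd"},
    ),
}


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment's true means, replicate-level dispersions and size."""

    label: str
    group: str
    mean_map: Mapping[str, float]
    sd_map: Mapping[str, float] = field(default_factory=dict)
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.sd_map) - set(self.mean_map)
        if unknown:
            raise ValueError(f"sd_map keys missing from mean_map: {sorted(unknown)}")
        for k, v in self.sd_map.items():
            if v < 0:
                raise ValueError(f"negative sd for {k!r}")

    def sd(self, quantity: str) -> float:
        return float(self.sd_map.get(quantity, 0.0))

    def mean(self, quantity: str, default=None) -> float:
        if quantity in self.mean_map:
            return float(self.mean_map[quantity])
        if default is None:
            raise ValueError(f"treatment {self.label!r} lacks quantity {quantity!r}")
        return float(default)


@dataclass(frozen=True)
class ExperimentDesign:
    """A whole experiment: kind, treatments, geometry, timing and seed."""

    kind: str
    treatments: Sequence[TreatmentSpec]
    bottle_volume: float = 1.0  # L
    duration: float = 2.0  # days
    light_hours_per_day: float = 12.0
    seed: int = 0
    probe_max_o2: float | None = None  # µmol L^-1; None = unbounded probe
    temperature: float = 298.15  # K
    external_pressure: float = 101325.0  # Pa

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("duration must be strictly positive")
        if not 0 <= self.light_hours_per_day <= 24:
            raise ValueError("light_hours_per_day must lie in [0, 24]")

    def validate_quantities(self) -> None:
        required, optional = _QUANTITIES[self.kind]
        for t in self.treatments:
            unknown = set(t.mean_map) - required - optional
            if unknown:
                raise ValueError(
                    f"unknown quantities for kind {self.kind!r} in treatment "
                    f"{t.label!r}: {sorted(unknown)}"
                )
            need = required if t.group != "control" else required & set(t.mean_map)
            missing = (required - set(t.mean_map)) if t.group != "control" else set()
            if missing:
                raise ValueError(
                    f"treatment {t.label!r} missing quantities: {sorted(missing)}"
                )


def _rng(design: ExperimentDesign, treatment: TreatmentSpec) -> np.random.Generator:
    """Deterministic substream keyed by (seed, kind, treatment label)."""
    return np.random.default_rng(
        [int(design.seed) & 0x7FFFFFFF,
         KINDS.index(design.kind),
         zlib.crc32(treatment.label.encode())]
    )


def _trunc_normal(rng, mean, sd, size, low=0.0, high=None, max_iter=1000):
    """Gaussian truncated to [low, high] by resampling.

    Resampling (rather than clipping) keeps the mean approximately calibrated
    at small coefficients of variation; sd = 0 returns the mean exactly.
    """
    mean = float(mean)
    if sd == 0:
        if (low is not None and mean < low) or (high is not None and mean > high):
            raise ValueError(f"mean {mean} outside truncation bounds [{low}, {high}]")
        return np.full(size, mean)
    x = rng.normal(mean, sd, size)
    for _ in range(max_iter):
        bad = np.zeros(x.shape, dtype=bool)
        if low is not None:
            bad |= x < low
        if high is not None:
            bad |= x > high
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("truncated-normal resampling did not converge")


def _lognormal_from_mean_sd(rng, mean, sd, size):
    """Log-normal draws matched to an arithmetic mean and sd; sd=0 -> mean."""
    if mean <= 0:
        raise ValueError("log-normal mean must be strictly positive")
    if sd == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


# ---------------------------------------------------------------------------
# generators

def generate_dark_incubation(design: ExperimentDesign) -> pd.DataFrame:
    """Dark-incubation endpoint table: one row per bottle.

    DOC, dissolved O2 (µmol L^-1) and cell abundance (cells L^-1) at the
    start and end of the dark period.  End DOC is truncated to
    [0, start DOC] in consuming treatments (mean end <= mean start), so no
    bottle fabricates organic carbon.
    """
    if design.kind != "dark_incubation":
        raise ValueError("design.kind must be 'dark_incubation'")
    design.validate_quantities()
    rows = []
    for t in design.treatments:
        rng = _rng(design, t)
        n = t.n_replicates
        doc_start = _trunc_normal(rng, t.mean("DOC_start"), t.sd("DOC_start"), n)
        consuming = t.mean("DOC_end") <= t.mean("DOC_start")
        doc_end = np.empty(n)
        for i in range(n):
            high = doc_start[i] if consuming else None
            doc_end[i] = _trunc_normal(
                rng, min(t.mean("DOC_end"), doc_start[i]) if consuming else t.mean("DOC_end"),
                t.sd("DOC_end"), 1, high=high,
            )[0]
        o2_start = _trunc_normal(rng, t.mean("O2_start"), t.sd("O2_start"), n)
        o2_end = _trunc_normal(rng, t.mean("O2_end"), t.sd("O2_end"), n)
        cells_start = _trunc_normal(rng, t.mean("cells_start"), t.sd("cells_start"), n)
        cells_end = _trunc_normal(rng, t.mean("cells_end"), t.sd("cells_end"), n)
        for i in range(n):
            rows.append({
                "treatment": t.label, "group": t.group, "replicate": i + 1,
                "DOC_start": doc_start[i], "DOC_end": doc_end[i],
                "O2_start": o2_start[i], "O2_end": o2_end[i],
                "cells_start": cells_start[i], "cells_end": cells_end[i],
                "bottle_volume": design.bottle_volume,
                "duration_days": design.duration,
            })
    return pd.DataFrame(rows)


def generate_pop_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Sealed producer-chamber table: dissolved endpoints plus headspace.

    Controls carry no headspace (gas_volume = 0) and no producer area.
    Dissolved end concentrations above ``design.probe_max_o2`` are clamped
    to the probe maximum and flagged ``diss_lower_bound`` — the stored value
    is a stated lower bound, never imputed.
    """
    if design.kind != "pop_chamber":
        raise ValueError("design.kind must be 'pop_chamber'")
    design.validate_quantities()
    rows = []
    for t in design.treatments:
        rng = _rng(design, t)
        n = t.n_replicates
        is_control = t.group == "control"
        if is_control:
            area = np.full(n, np.nan)
            gas_vol = np.zeros(n)
            gas_frac = np.zeros(n)
        else:
            area = _trunc_normal(rng, t.mean("surface_area"), t.sd("surface_area"), n,
                                 low=1e-9)
            gas_vol = _trunc_normal(rng, t.mean("gas_volume"), t.sd("gas_volume"), n)
            f_mean = t.mean("gas_O2_fraction")
            if not 0 <= f_mean <= 1:
                raise ValueError("gas_O2_fraction must lie in [0, 1]")
            gas_frac = _trunc_normal(rng, f_mean, t.sd("gas_O2_fraction"), n, high=1.0)
        o2_start = _trunc_normal(rng, t.mean("O2_diss_start", 0.0),
                                 t.sd("O2_diss_start"), n)
        o2_end_true = _trunc_normal(rng, t.mean("O2_diss_end", 0.0),
                                    t.sd("O2_diss_end"), n)
        if design.probe_max_o2 is not None:
            lower_bound = o2_end_true > design.probe_max_o2
            o2_end = np.minimum(o2_end_true, design.probe_max_o2)
        else:
            lower_bound = np.zeros(n, dtype=bool)
            o2_end = o2_end_true
        cells_end = (
            _trunc_normal(rng, t.mean("cells_end"), t.sd("cells_end"), n)
            if "cells_end" in t.mean_map else np.full(n, np.nan)
        )
        for i in range(n):
            rows.append({
                "treatment": t.label, "group": t.group, "replicate": i + 1,
                "surface_area": area[i],
                "chamber_volume": design.bottle_volume,
                "duration_days": design.duration,
                "light_hours": design.duration * design.light_hours_per_day,
                "O2_diss_start": o2_start[i], "O2_diss_end": o2_end[i],
                "diss_lower_bound": bool(lower_bound[i]),
                "gas_volume": gas_vol[i], "gas_O2_fraction": gas_frac[i],
                "cells_end": cells_end[i],
                "temperature": design.temperature,
                "external_pressure": design.external_pressure,
            })
    return pd.DataFrame(rows)


def generate_open_tank(design: ExperimentDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Open-tank run: per-minute bubble counts plus measured diameters.

    Counts are a homogeneous Poisson process at the configured
    area-normalized rate times tank producer area; diameters are log-normal
    draws matched to the configured mean/sd, at least 40 per treatment.
    Returns ``(counts, diameters)``.
    """
    if design.kind != "open_tank":
        raise ValueError("design.kind must be 'open_tank'")
    design.validate_quantities()
    count_rows, diam_rows = [], []
    for t in design.treatments:
        rng = _rng(design, t)
        rate = t.mean("bubbles_per_min_per_dm2")
        if rate < 0:
            raise ValueError("bubble rate must be non-negative")
        area = t.mean("surface_area_dm2")
        minutes = int(round(t.mean("duration_min")))
        par = t.mean("PAR", default=150.0)
        d_mean = t.mean("bubble_diameter_mean")
        if d_mean <= 0:
            raise ValueError("bubble diameter mean must be strictly positive")
        d_sd = t.mean("bubble_diameter_sd")
        for rep in range(1, t.n_replicates + 1):
            counts = rng.poisson(rate * area, size=minutes)
            for minute, c in enumerate(counts, start=1):
                count_rows.append({
                    "treatment": t.label, "group": t.group, "replicate": rep,
                    "minute": minute, "count": int(c),
                    "surface_area_dm2": area, "PAR": par,
                })
        n_meas = max(40, int(t.mean("n_bubbles_measured", default=40)))
        for d in _lognormal_from_mean_sd(rng, d_mean, d_sd, n_meas):
            diam_rows.append({"treatment": t.label, "group": t.group,
                              "diameter_mm": float(d)})
    return pd.DataFrame(count_rows), pd.DataFrame(diam_rows)


def generate_cell_sizes(design: ExperimentDesign) -> pd.DataFrame:
    """Microscopy cell-dimension table: one row per measured cell.

    Volumes are log-normal around the configured median (``volume_median``,
    µm^3; log-sd ``volume_sigma_log``); the cylinder-with-caps geometry is
    inverted through the aspect ratio a = length/width >= 1 to yield
    dimensions with length >= width > 0.  ``n_replicates`` counts measured
    cells.
    """
    if design.kind != "cell_sizes":
        raise ValueError("design.kind must be 'cell_sizes'")
    design.validate_quantities()
    rows = []
    for t in design.treatments:
        rng = _rng(design, t)
        n = t.n_replicates
        median = t.mean("volume_median")
        if median <= 0:
            raise ValueError("volume_median must be strictly positive")
        sigma = t.mean("volume_sigma_log", default=0.0)
        volumes = (np.full(n, median) if sigma == 0
                   else rng.lognormal(np.log(median), sigma, n))
        aspect = _trunc_normal(rng, t.mean("aspect_mean"),
                               t.mean("aspect_sd", default=0.0), n, low=1.0)
        # V = (pi/4) w^3 (a - 1/3)  =>  w = (4V / (pi (a - 1/3)))^(1/3)
        width = (4.0 * volumes / (np.pi * (aspect - 1.0 / 3.0))) ** (1.0 / 3.0)
        length = aspect * width
        for i in range(n):
            rows.append({
                "treatment": t.label, "group": t.group, "cell_id": i + 1,
                "length_um": length[i], "width_um": width[i],
                "volume_um3": volumes[i],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default study conditions
#
# Means follow the printed treatment-level summaries of the source study
# (net dissolved production 5.99 / 6.33 µmol cm^-2 day^-1 for fleshy /
# calcifying producers; gas fractions 37.33 / 13.78 / 10.19 / 5.00 %;
# Chaetomorpha ebullition 10.3 bubbles min^-1 dm^-2; bubble diameters
# 0.64 / 0.79 mm; cell volumes ~0.1 µm^3).  Replicate-level dispersions are
# not published: gas fractions use the printed per-treatment SE * sqrt(n),
# net dissolved rates a 25% CV (the published group SEs mix organisms, so
# they overstate within-treatment spread and would imply bottles with
# negative production), and the rest are placeholder defaults at realistic
# coefficients of variation.

_SQRT5 = float(np.sqrt(5.0))


def _pop_treatment(label, group, net_rate, gas_frac_target, area=10.0,
                   chamber_volume=2.0, days=4.0, net_rate_sd=0.0,
                   gas_frac_sd=0.0, cells_end=np.nan, cells_sd_rel=0.15,
                   o2_start=210.0, n=5):
    """Build a POP TreatmentSpec from target display-unit rates.

    ``net_rate`` (µmol cm^-2 day^-1) and a target gas fraction are converted
    to the endpoint concentrations and headspace volumes the generator
    draws; ``net_rate_sd`` and ``gas_frac_sd`` are replicate-level sds of
    the derived rate and fraction, mapped back onto the drawn quantities
    (the gas-volume sd is reduced by the part of the fraction variance that
    the net-rate noise already contributes).
    """
    delta_o2 = net_rate * area * days / chamber_volume  # µmol L^-1
    gas_rate = net_rate * gas_frac_target / (1.0 - gas_frac_target)
    n_gas_umol = gas_rate * area * days
    # headspace at 1 atm, 298.15 K, pure-ish O2 fraction 0.9 of bubble gas
    gas_o2_fraction = 0.9
    gas_volume_ml = n_gas_umol * 1e-6 * 8.314 * 298.15 / 101325.0 / gas_o2_fraction * 1e6
    delta_sd = net_rate_sd * area * days / chamber_volume
    if gas_frac_sd > 0 and gas_rate > 0:
        total = net_rate + gas_rate
        dfrac_dgas = net_rate / total**2
        dfrac_dnet = gas_rate / total**2
        from_net = dfrac_dnet * net_rate_sd
        gas_part = math.sqrt(max(gas_frac_sd**2 - from_net**2, 0.0))
        gas_rate_sd = gas_part / dfrac_dgas
        gas_vol_sd = gas_volume_ml * gas_rate_sd / gas_rate
    else:
        gas_vol_sd = 0.0
    mean_map = {
        "surface_area": area,
        "O2_diss_start": o2_start, "O2_diss_end": o2_start + delta_o2,
        "gas_volume": gas_volume_ml, "gas_O2_fraction": gas_o2_fraction,
    }
    sd_map = {
        "surface_area": 0.05 * area,
        "O2_diss_start": 2.0, "O2_diss_end": delta_sd,
        "gas_volume": gas_vol_sd, "gas_O2_fraction": 0.02,
    }
    if np.isfinite(cells_end):
        mean_map["cells_end"] = cells_end
        sd_map["cells_end"] = cells_sd_rel * cells_end
    return TreatmentSpec(label, group, mean_map, sd_map, n_replicates=n)


def default_dark_design(seed: int = 0) -> ExperimentDesign:
    """48-h dark incubation with exudates of five treatments, n = 5.

    Calibrated so fleshy treatments show the higher cell-specific DOC demand
    and all treatments share the same cell-specific O2 demand (~3e-8 µmol
    per cell over the incubation), the study's hallmark of overflow
    metabolism in algal exudates.
    """
    def spec(label, group, doc0, doc1, o20, o21, c0, c1):
        return TreatmentSpec(
            label, group,
            mean_map={"DOC_start": doc0, "DOC_end": doc1, "O2_start": o20,
                      "O2_end": o21, "cells_start": c0, "cells_end": c1},
            sd_map={"DOC_start": 3.0, "DOC_end": 3.0, "O2_start": 2.0,
                    "O2_end": 4.0, "cells_start": 0.1 * c0, "cells_end": 0.15 * c1},
            n_replicates=5,
        )
    return ExperimentDesign(
        kind="dark_incubation",
        treatments=[
            spec("coral", "calcifying", 60.0, 51.0, 210.0, 196.5, 0.5e9, 0.95e9),
            spec("CCA", "calcifying", 62.0, 52.0, 210.0, 195.0, 0.5e9, 1.0e9),
            spec("turf", "fleshy", 75.0, 43.0, 210.0, 186.0, 0.5e9, 1.3e9),
            spec("macroalgae", "fleshy", 80.0, 44.0, 210.0, 183.0, 0.5e9, 1.4e9),
            TreatmentSpec(
                "control", "control",
                mean_map={"DOC_start": 45.0, "DOC_end": 43.0, "O2_start": 210.0,
                          "O2_end": 207.0, "cells_start": 0.5e9, "cells_end": 0.6e9},
                sd_map={"DOC_start": 2.0, "DOC_end": 2.0, "O2_start": 2.0,
                        "O2_end": 2.0, "cells_start": 0.05e9, "cells_end": 0.06e9},
                n_replicates=5,
            ),
        ],
        bottle_volume=1.0, duration=2.0, light_hours_per_day=0.0, seed=seed,
    )


def default_pop_design(seed: int = 0) -> ExperimentDesign:
    """Four-day sealed-chamber experiment, five producers, n = 5.

    Net dissolved rates and gas fractions match the printed treatment means
    (6.33 calcifying / 5.99 fleshy µmol cm^-2 day^-1; gas fractions 5.00,
    10.19, 13.78, 37.33 %); sustained endpoint microbial abundances are set
    so the dark per-cell respiration scales to volumetric respiration of the
    order the budget model uses.
    """
    return ExperimentDesign(
        kind="pop_chamber",
        treatments=[
            _pop_treatment("coral", "calcifying", 6.33, 0.0500,
                           net_rate_sd=0.25 * 6.33, gas_frac_sd=0.0555 * _SQRT5,
                           cells_end=5.2e8),
            _pop_treatment("CCA", "calcifying", 6.33, 0.1019,
                           net_rate_sd=0.25 * 6.33, gas_frac_sd=0.0288 * _SQRT5,
                           cells_end=6.0e8),
            _pop_treatment("turf", "fleshy", 6.10, 0.1378,
                           net_rate_sd=0.25 * 6.10, gas_frac_sd=0.0133 * _SQRT5,
                           cells_end=2.5e9),
            _pop_treatment("macroalgae", "fleshy", 5.99, 0.3733,
                           net_rate_sd=0.25 * 5.99, gas_frac_sd=0.0834 * _SQRT5,
                           cells_end=4.9e9),
            TreatmentSpec(
                "control", "control",
                mean_map={"O2_diss_start": 210.0, "O2_diss_end": 210.0,
                          "gas_volume": 0.0, "gas_O2_fraction": 0.0},
                sd_map={"O2_diss_start": 2.0, "O2_diss_end": 5.0},
                n_replicates=5,
            ),
        ],
        bottle_volume=2.0, duration=4.0, light_hours_per_day=12.0, seed=seed,
        probe_max_o2=625.0,
    )


def default_open_tank_design(seed: int = 0) -> ExperimentDesign:
    """Open-tank bubble counting: one 60-min run per organism at 150 PAR."""
    def spec(label, group, rate, d_mean, d_sd, area=1.0):
        return TreatmentSpec(
            label, group,
            mean_map={"bubbles_per_min_per_dm2": rate,
                      "bubble_diameter_mean": d_mean, "bubble_diameter_sd": d_sd,
                      "surface_area_dm2": area, "duration_min": 60.0,
                      "PAR": 150.0},
            n_replicates=1,
        )
    return ExperimentDesign(
        kind="open_tank",
        treatments=[
            spec("Chaetomorpha", "fleshy", 10.3, 0.64, 0.23),
            spec("Gracilaria", "fleshy", 1.29, 0.79, 0.27),
            spec("Favia", "calcifying", 0.10, 0.64, 0.23),
            spec("Montipora", "calcifying", 0.006, 0.64, 0.23),
        ],
        bottle_volume=9.0, duration=60.0 / 1440.0, seed=seed,
    )


def default_cell_size_design(seed: int = 0, n_cells: int = 400) -> ExperimentDesign:
    """Microscopy cell sizes: volumes around the ~0.1 µm^3 community median.

    Cells shrink on calcifier exudates and swell on fleshy-algal exudates
    relative to the starting community.
    """
    def spec(label, group, median):
        return TreatmentSpec(
            label, group,
            mean_map={"volume_median": median, "volume_sigma_log": 0.45,
                      "aspect_mean": 1.6, "aspect_sd": 0.3},
            n_replicates=n_cells,
        )
    return ExperimentDesign(
        kind="cell_sizes",
        treatments=[
            spec("T0h", "control", 0.10),
            spec("control", "control", 0.10),
            spec("coral", "calcifying", 0.07),
            spec("CCA", "calcifying", 0.08),
            spec("turf", "fleshy", 0.14),
            spec("macroalgae", "fleshy", 0.16),
        ],
        duration=4.0, seed=seed,
    )


# ---------------------------------------------------------------------------
# persistence

def _design_to_dict(design: ExperimentDesign) -> dict:
    d = dataclasses.asdict(design)
    d["treatments"] = [
        {**dataclasses.asdict(t),
         "mean_map": dict(t.mean_map), "sd_map": dict(t.sd_map)}
        for t in design.treatments
    ]
    return d


def save_table(df: pd.DataFrame, path, design: ExperimentDesign | None = None) -> None:
    """Write a generated table as CSV with a sidecar design/seed record."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if design is not None:
        meta = {"design": _design_to_dict(design), "seed": design.seed}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, default=float)
        )
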