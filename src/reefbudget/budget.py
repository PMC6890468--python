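"""Weighted mixing model of reef oxygen loss under varying algal cover.

An idealized 1 m^2 of benthos is covered by a mixture of coral (fraction
C = 1 - A) and fleshy algae (fraction A), with the microbial community of the
1 m^3 boundary-layer water column above it.  Each producer class carries
three area-scaled O2 rates: net dissolved production rho_net (µmol m^-2 d^-1),
gaseous production rho_gas (µmol m^-2 d^-1), and the microbial respiration it
sustains per water volume, omega_microb (µmol m^-3 d^-1).  Gross production is

    O_diss  = rho_net * area + omega_microb * (area * depth)
    O_gross = O_diss + rho_gas * area

Reef-level quantities are linear mixtures, e.g.
O_reef_gross(A) = (1-A) * O_coral_gross + A * O_algae_gross, and the loss
fractions are ratios of mixtures:

    E(A) = O_reef_gas(A)    / O_reef_gross(A)   (ebullition)
    M(A) = O_reef_microb(A) / O_reef_gross(A)   (microbial respiration)

which, as a function of A, are shifted Hill functions of order one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProducerRates",
    "ReefModel",
    "gross_production",
    "mix",
    "ebullition_fraction",
    "microbial_fraction",
    "ebullition_fraction_hill",
    "microbial_fraction_hill",
    "solve_gross_ratio",
    "budget_curve",
    "model_from_fractions",
    "omega_from_cells",
]


@dataclass(frozen=True)
class ProducerRates:
    """Area-scaled O2 rates of one producer class.

    rho_net      : net dissolved O2 production, µmol m^-2 day^-1 (may be < 0)
    rho_gas      : gaseous O2 production, µmol m^-2 day^-1
    omega_microb : microbial dissolved-O2 respiration sustained by this
                   producer, µmol m^-3 day^-1 of boundary-layer water
    """

    rho_net: float
    rho_gas: float
    omega_microb: float

    def __post_init__(self) -> None:
        if self.rho_gas < 0:
            raise ValueError("rho_gas must be non-negative")
        if self.omega_microb < 0:
            raise ValueError("omega_microb must be non-negative")


@dataclass(frozen=True)
class ReefModel:
    """Two-producer reef: coral (cover 1-A) and fleshy algae (cover A)."""

    coral: ProducerRates
    algae: ProducerRates
    boundary_layer_depth: float = 1.0  # m
    benthic_area: float = 1.0  # m^2

    def __post_init__(self) -> None:
        for name, p in (("coral", self.coral), ("algae", self.algae)):
            _, gross = gross_production(p, self.benthic_area, self.boundary_layer_depth)
            if not gross > 0:
                raise ValueError(f"gross production of {name} must be strictly positive")

    # Per-producer totals used throughout; evaluated at the model geometry.
    def _totals(self, p: ProducerRates) -> tuple[float, float, float]:
        diss, gross = gross_production(p, self.benthic_area, self.boundary_layer_depth)
        gas = p.rho_gas * self.benthic_area
        microb = p.omega_microb * self.benthic_area * self.boundary_layer_depth
        return gross, gas, microb


def gross_production(
    p: ProducerRates, area: float = 1.0, depth: float = 1.0
) -> tuple[float, float]:
    """(O_diss, O_gross) per ``area`` m^2 of this producer.

    Microbial respiration is added back to the net dissolved accumulation to
    recover the dissolved gross, then the gas term completes the total.
    """
    o_diss = p.rho_net * area + p.omega_microb * (area * depth)
    o_gross = o_diss + p.rho_gas * area
    return o_diss, o_gross


def mix(model: ReefModel, algal_cover) -> tuple:
    """Reef-level (O_gross, O_gas, O_microb) at algal cover fraction A.

    Linear weighting with coral cover C = 1 - A.  ``algal_cover`` may be a
    scalar or an array in [0, 1].
    """
    a = np.asarray(algal_cover, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("algal cover must lie in [0, 1]")
    gc, lc_gas, lc_mic = model._totals(model.coral)
    ga, la_gas, la_mic = model._totals(model.algae)
    c = 1.0 - a
    out = (c * gc + a * ga, c * lc_gas + a * la_gas, c * lc_mic + a * la_mic)
    if np.isscalar(algal_cover):
        return tuple(float(x) for x in out)
    return out


def _loss_fraction(model: ReefModel, algal_cover, which: str):
    gross, gas, microb = mix(model, algal_cover)
    loss = gas if which == "gas" else microb
    gross_arr = np.asarray(gross, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(gross_arr > 0, np.asarray(loss) / gross_arr, np.nan)
    return float(frac) if np.isscalar(algal_cover) else frac


def ebullition_fraction(model: ReefModel, algal_cover):
    """E(A) = O_reef_gas / O_reef_gross; NaN where gross vanishes."""
    return _loss_fraction(model, algal_cover, "gas")


def microbial_fraction(model: ReefModel, algal_cover):
    """M(A) = O_reef_microb / O_reef_gross; NaN where gross vanishes."""
    return _loss_fraction(model, algal_cover, "microb")


def _hill_fraction(model: ReefModel, algal_cover, which: str):
    """Closed-form shifted Hill function of order one.

    With dG = O_algae_gross - O_coral_gross and dL the matching loss-term
    difference,

        F(A) = [ (dL/dG) A + L_coral/dG ] / [ G_coral/dG + A ].

    Algebraically identical to the direct mixture ratio; if dG = 0 the Hill
    form is undefined and the direct form is used.
    """
    gc, lc_gas, lc_mic = model._totals(model.coral)
    ga, la_gas, la_mic = model._totals(model.algae)
    lc, la = (lc_gas, la_gas) if which == "gas" else (lc_mic, la_mic)
    dg = ga - gc
    if dg == 0.0:
        return _loss_fraction(model, algal_cover, which)
    a = np.asarray(algal_cover, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("algal cover must lie in [0, 1]")
    dl = la - lc
    out = ((dl / dg) * a + lc / dg) / (gc / dg + a)
    return float(out) if np.isscalar(algal_cover) else out


def ebullition_fraction_hill(model: ReefModel, algal_cover):
    """E(A) in shifted-Hill form; equals :func:`ebullition_fraction`."""
    return _hill_fraction(model, algal_cover, "gas")


def microbial_fraction_hill(model: ReefModel, algal_cover):
    """M(A) in shifted-Hill form; equals :func:`microbial_fraction`."""
    return _hill_fraction(model, algal_cover, "microb")


def solve_gross_ratio(m0: float, m1: float, m_at: float, algal_cover: float) -> float:
    """Invert the mixing model for r = O_algae_gross / O_coral_gross.

    Given a loss fraction m0 at A=0, m1 at A=1, and the observed fraction
    ``m_at`` at intermediate cover A, the mixture ratio satisfies

        r = (1 - A) (m_at - m0) / [ A (m1 - m_at) ].

    ``m_at`` must lie strictly between m0 and m1; re-evaluating the mixture
    with this r reproduces ``m_at`` exactly.
    """
    if not 0 < algal_cover < 1:
        raise ValueError("algal cover must lie strictly inside (0, 1)")
    lo, hi = min(m0, m1), max(m0, m1)
    if not lo < m_at < hi:
        raise ValueError("intermediate fraction must lie strictly between the endpoints")
    return (1.0 - algal_cover) * (m_at - m0) / (algal_cover * (m1 - m_at))


def model_from_fractions(
    m0: float, e0: float, m1: float, e1: float, gross_ratio: float,
    coral_gross: float = 1.0,
) -> ReefModel:
    """Synthetic reef model calibrated to endpoint loss fractions.

    Reconstructs ProducerRates from the single-producer microbial fractions
    (m0 coral, m1 algae), ebullition fractions (e0, e1) and the gross ratio
    r = O_algae_gross/O_coral_gross, with coral gross production fixed at
    ``coral_gross`` (arbitrary units).  Useful when only the loss fractions
    of a budget are known, not the underlying rates.
    """
    ga = gross_ratio * coral_gross
    coral = ProducerRates(
        rho_net=coral_gross * (1.0 - m0 - e0),
        rho_gas=coral_gross * e0,
        omega_microb=coral_gross * m0,
    )
    algae = ProducerRates(
        rho_net=ga * (1.0 - m1 - e1),
        rho_gas=ga * e1,
        omega_microb=ga * m1,
    )
    return ReefModel(coral=coral, algae=algae)


def omega_from_cells(per_cell_respiration_umol_day: float, cells_per_liter: float) -> float:
    """Microbial volumetric respiration, µmol m^-3 day^-1.

    per-cell dark respiration (µmol O2 cell^-1 day^-1) times the sustained
    cell concentration, converted from cells L^-1 to cells m^-3.
    """
    if per_cell_respiration_umol_day < 0 or cells_per_liter < 0:
        raise ValueError("rates and concentrations must be non-negative")
    return per_cell_respiration_umol_day * cells_per_liter * 1000.0


def budget_curve(model: ReefModel, grid=None) -> pd.DataFrame:
    """Evaluate E, M and the combined loss fraction on a cover grid.

    Returns a DataFrame with columns ``algal_cover``, ``E``, ``M``,
    ``combined`` (= E + M elementwise).  Default grid: 0 to 1 step 0.01.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    e = ebullition_fraction(model, grid)
    m = microbial_fraction(model, grid)
    return pd.DataFrame(
        {"algal_cover": grid, "E": e, "M": m, "combined": e + m}
    )
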