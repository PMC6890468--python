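"""Derived-rate operations against hand values and brute-force oracles."""

import math

import numpy as np
import pytest

from conftest import zero_noise
from reefbudget import rates as rt
from reefbudget import synthetic as syn
from reefbudget.rates import BiomassCoefficients


# ---------------------------------------------------------------------------
# cell-specific demands

def test_cell_specific_demand_hand_values():
    # 10 µmol/L consumed over a 1e9 cells/L yield
    assert rt.cell_specific_demand(10.0, 0.0, 0.0, 1e9) == pytest.approx(1e-8)
    assert rt.cell_specific_demand(5.0, 5.0, 0.0, 1e9) == 0.0


def test_nonpositive_cell_yield_is_flagged_not_raised():
    assert math.isnan(rt.cell_specific_demand(10.0, 0.0, 2e9, 1e9))
    assert math.isnan(rt.cell_specific_demand(10.0, 0.0, 1e9, 1e9))


def test_demand_oracle_on_random_records():
    rng = np.random.default_rng(42)
    start = rng.uniform(20, 100, 100)
    end = rng.uniform(0, 20, 100)
    c0 = rng.uniform(1e8, 1e9, 100)
    c1 = c0 + rng.uniform(1e8, 1e9, 100)
    got = rt.cell_specific_demand(start, end, c0, c1)
    for i in range(100):
        want = (start[i] - end[i]) / (c1[i] - c0[i])
        assert got[i] == pytest.approx(want, rel=1e-12)


def test_flagged_bottles_drop_out_of_summaries(dark_design):
    df = syn.generate_dark_incubation(dark_design)
    df.loc[df.index[0], "cells_end"] = 0.0  # kill the yield of one bottle
    out = rt.cell_specific_demands(df)
    assert not out["demand_defined"].iloc[0]
    summ = rt.summarize(out, "DOC_demand")
    first = summ[summ["treatment"] == df["treatment"].iloc[0]]
    assert int(first["DOC_demand_n"].iloc[0]) == dark_design.treatments[0].n_replicates - 1


# ---------------------------------------------------------------------------
# cell geometry and biomass

def test_cell_volume_hand_values():
    assert rt.cell_volume(1.0, 1.0) == pytest.approx(math.pi / 6)
    assert rt.cell_volume(2.0, 1.0) == pytest.approx((math.pi / 4) * (2 - 1 / 3))
    with pytest.raises(ValueError):
        rt.cell_volume(0.5, 1.0)


def test_cell_volume_decomposes_into_cylinder_plus_sphere():
    rng = np.random.default_rng(0)
    w = rng.uniform(0.2, 1.5, 100)
    length = w + rng.uniform(0, 3, 100)
    got = rt.cell_volume(length, w)
    cylinder = (math.pi / 4) * w**2 * (length - w)
    sphere = (math.pi / 6) * w**3
    assert np.allclose(got, cylinder + sphere, rtol=1e-12)


def test_biomass_power_law():
    ident = BiomassCoefficients(scale=1.0, exponent=1.0)
    assert rt.biomass_from_volume(0.5, ident) == 0.5
    assert rt.biomass_from_volume(0.0) == 0.0
    coeffs = BiomassCoefficients()
    ratio = rt.biomass_from_volume(0.2, coeffs) / rt.biomass_from_volume(0.1, coeffs)
    assert ratio == pytest.approx(2**coeffs.exponent)


def test_biomass_change_per_area():
    ident = BiomassCoefficients(scale=1.0, exponent=1.0)
    # no change
    assert rt.biomass_change_per_area(1e9, 0.1, 1e9, 0.1, 1.0, 10.0, ident) == 0.0
    # doubling abundance at constant volume adds one starting biomass
    got = rt.biomass_change_per_area(1e9, 0.1, 2e9, 0.1, 2.0, 10.0, ident)
    assert got == pytest.approx(1e9 * 0.1 * 2.0 / 10.0)
    # sign preserved for shrinking communities
    assert rt.biomass_change_per_area(1e9, 0.1, 5e8, 0.1, 1.0, 10.0, ident) < 0
    # random tables vs per-cell mass recomputation
    rng = np.random.default_rng(3)
    for _ in range(50):
        a0, a1 = rng.uniform(1e8, 2e9, 2)
        v0, v1 = rng.uniform(0.05, 0.3, 2)
        vol, area = rng.uniform(0.5, 5), rng.uniform(5, 50)
        want = (a1 * 435.0 * v1**0.86 - a0 * 435.0 * v0**0.86) * vol / area
        got = rt.biomass_change_per_area(a0, v0, a1, v1, vol, area)
        assert got == pytest.approx(want, rel=1e-12)


# ---------------------------------------------------------------------------
# POP rates

def test_pop_dissolved_rate_hand_value():
    assert rt.pop_dissolved_production_rate(0.0, 50.0, 2.0, 10.0, 2.0) == pytest.approx(5.0)
    assert rt.pop_dissolved_production_rate(100.0, 100.0, 2.0, 10.0, 2.0) == 0.0
    with pytest.raises(ValueError):
        rt.pop_dissolved_production_rate(0.0, 50.0, 2.0, 0.0, 2.0)


def test_pop_gas_rate_ideal_gas_hand_value():
    # 5 mL at 35% O2, 1 atm, 298.15 K -> 71.53 µmol; over 10 cm^2, 2 days
    n = rt.pop_gas_moles_umol(5.0, 0.35)
    assert n == pytest.approx(101325 * 1.75e-6 / (8.314 * 298.15) * 1e6, rel=1e-12)
    assert n == pytest.approx(71.5, abs=0.05)
    rate = rt.pop_gas_production_rate(5.0, 0.35, 10.0, 2.0)
    assert rate == pytest.approx(n / 20.0, rel=1e-12)
    assert rt.pop_gas_production_rate(0.0, 0.35, 10.0, 2.0) == 0.0


def test_gas_rate_linear_in_o2_fraction():
    r1 = rt.pop_gas_production_rate(5.0, 0.2, 10.0, 2.0)
    r2 = rt.pop_gas_production_rate(5.0, 0.4, 10.0, 2.0)
    assert r2 == pytest.approx(2 * r1, rel=1e-12)


def test_gas_fraction_cases():
    assert rt.gas_fraction(0.0, 5.0) == 0.0
    assert rt.gas_fraction(3.0, 3.0) == 0.5
    assert math.isnan(rt.gas_fraction(0.0, 0.0))
    assert math.isnan(rt.gas_fraction(1.0, -2.0))


def test_rate_oracle_on_random_records():
    rng = np.random.default_rng(7)
    n = 1000
    o2s = rng.uniform(150, 250, n)
    o2e = o2s + rng.uniform(-50, 150, n)
    vol = rng.uniform(0.5, 5, n)
    area = rng.uniform(1, 50, n)
    days = rng.uniform(1, 5, n)
    gasv = rng.uniform(0, 10, n)
    gasf = rng.uniform(0, 1, n)
    diss = rt.pop_dissolved_production_rate(o2s, o2e, vol, area, days)
    gas = rt.pop_gas_production_rate(gasv, gasf, area, days)
    for i in range(n):
        want_d = (o2e[i] - o2s[i]) * vol[i] / (area[i] * days[i])
        want_g = (101325.0 * gasv[i] * 1e-6 * gasf[i] / (8.314 * 298.15)) * 1e6 / (
            area[i] * days[i]
        )
        assert diss[i] == pytest.approx(want_d, rel=1e-12, abs=1e-15)
        assert gas[i] == pytest.approx(want_g, rel=1e-12, abs=1e-15)


# ---------------------------------------------------------------------------
# open tank

def test_open_tank_rate_hand_values():
    assert rt.open_tank_rate(618, 60.0, 1.0) == pytest.approx(10.3)
    assert rt.open_tank_rate(0, 60.0, 1.0) == 0.0
    assert rt.open_tank_rate(618, 60.0, 2.0) == pytest.approx(10.3 / 2)


def test_open_tank_table_collapse(tank_design):
    counts, _ = syn.generate_open_tank(tank_design)
    rates = rt.open_tank_rates(counts)
    chaeto = rates[rates["treatment"] == "Chaetomorpha"].iloc[0]
    assert chaeto["minutes"] == 60
    want = chaeto["total_bubbles"] / 60.0 / chaeto["surface_area_dm2"]
    assert chaeto["rate"] == pytest.approx(want, rel=1e-12)


# ---------------------------------------------------------------------------
# zero-noise calibration through the whole rate layer

def test_zero_noise_cohort_means_equal_configured_targets(pop_design):
    pop = syn.generate_pop_experiment(zero_noise(pop_design))
    rates = rt.pop_rates(pop)
    summ = rt.summarize(rates, ["net_dissolved_rate", "gas_frac"])
    macro = summ[summ["treatment"] == "macroalgae"].iloc[0]
    assert macro["net_dissolved_rate_mean"] == pytest.approx(5.99, rel=1e-9)
    assert macro["gas_frac_mean"] == pytest.approx(0.3733, rel=1e-9)
    coral = summ[summ["treatment"] == "coral"].iloc[0]
    assert coral["net_dissolved_rate_mean"] == pytest.approx(6.33, rel=1e-9)
    assert coral["gas_frac_mean"] == pytest.approx(0.05, rel=1e-9)
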