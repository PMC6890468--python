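"""Generators: determinism, calibration, physical bounds, error handling."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import zero_noise
from reefbudget import synthetic as syn
from reefbudget.synthetic import ExperimentDesign, TreatmentSpec


def _generate(design):
    gen = {
        "dark_incubation": syn.generate_dark_incubation,
        "pop_chamber": syn.generate_pop_experiment,
        "open_tank": lambda d: syn.generate_open_tank(d)[0],
        "cell_sizes": syn.generate_cell_sizes,
    }
    return gen[design.kind](design)


# ---------------------------------------------------------------------------
# determinism and stream independence

@pytest.mark.parametrize("factory", [
    syn.default_dark_design,
    syn.default_pop_design,
    syn.default_open_tank_design,
    lambda seed: syn.default_cell_size_design(seed, n_cells=50),
])
def test_same_seed_gives_identical_tables(factory):
    a = _generate(factory(7))
    b = _generate(factory(7))
    pd.testing.assert_frame_equal(a, b)
    c = _generate(factory(8))
    assert not a.drop(columns=["treatment", "group"]).equals(
        c.drop(columns=["treatment", "group"])
    )


def test_adding_a_treatment_does_not_perturb_others(dark_design):
    full = syn.generate_dark_incubation(dark_design)
    coral_only = dataclasses.replace(
        dark_design, treatments=[t for t in dark_design.treatments if t.label == "coral"]
    )
    sub = syn.generate_dark_incubation(coral_only)
    pd.testing.assert_frame_equal(
        full[full["treatment"] == "coral"].reset_index(drop=True), sub
    )


# ---------------------------------------------------------------------------
# calibration

def test_zero_noise_dark_records_equal_means():
    spec = TreatmentSpec(
        "x", "fleshy",
        mean_map={"DOC_start": 80.0, "DOC_end": 70.0, "O2_start": 210.0,
                  "O2_end": 200.0, "cells_start": 1e9, "cells_end": 2e9},
        n_replicates=3,
    )
    design = ExperimentDesign("dark_incubation", [spec], seed=1)
    df = syn.generate_dark_incubation(design)
    assert len(df) == 3
    for col, want in [("DOC_start", 80.0), ("DOC_end", 70.0),
                      ("O2_end", 200.0), ("cells_end", 2e9)]:
        assert (df[col] == want).all()


def test_zero_noise_pop_and_tank_and_cells_equal_means(pop_design, tank_design, cell_design):
    pop = syn.generate_pop_experiment(zero_noise(pop_design))
    for t in pop_design.treatments:
        if t.group == "control":
            continue
        sub = pop[pop["treatment"] == t.label]
        assert np.allclose(sub["gas_volume"], t.mean_map["gas_volume"])
        assert np.allclose(sub["O2_diss_end"], t.mean_map["O2_diss_end"])
    counts, diam = syn.generate_open_tank(zero_noise(tank_design))
    # Poisson counts are not sd-parameterized, but diameters collapse
    chaeto = diam[diam["treatment"] == "Chaetomorpha"]["diameter_mm"]
    assert chaeto.between(0, 10).all()


def test_diameter_sample_calibrated_to_configured_mean(tank_design):
    _, diam = syn.generate_open_tank(tank_design)
    d = diam[diam["treatment"] == "Chaetomorpha"]["diameter_mm"]
    assert len(d) >= 40
    se = 0.23 / np.sqrt(len(d))
    assert abs(d.mean() - 0.64) < 3 * se


def test_poisson_totals_within_counting_error(tank_design):
    counts, _ = syn.generate_open_tank(tank_design)
    total = counts[counts["treatment"] == "Chaetomorpha"]["count"].sum()
    expected = 10.3 * 60 * 1.0
    assert abs(total - expected) <= 3 * np.sqrt(expected)


def test_zero_rate_yields_zero_counts():
    spec = TreatmentSpec(
        "still", "calcifying",
        mean_map={"bubbles_per_min_per_dm2": 0.0, "bubble_diameter_mean": 0.5,
                  "bubble_diameter_sd": 0.1, "surface_area_dm2": 1.0,
                  "duration_min": 30.0},
        n_replicates=2,
    )
    counts, _ = syn.generate_open_tank(ExperimentDesign("open_tank", [spec], seed=3))
    assert (counts["count"] == 0).all()


# ---------------------------------------------------------------------------
# pop-chamber specifics

def test_controls_have_no_gas(pop_design):
    pop = syn.generate_pop_experiment(pop_design)
    controls = pop[pop["group"] == "control"]
    assert len(controls) and (controls["gas_volume"] == 0).all()


def test_probe_clamping_stores_lower_bound():
    spec = TreatmentSpec(
        "hot", "fleshy",
        mean_map={"surface_area": 10.0, "O2_diss_start": 200.0,
                  "O2_diss_end": 25.0 * 31.25,  # far above the probe max
                  "gas_volume": 1.0, "gas_O2_fraction": 0.9},
        n_replicates=4,
    )
    design = ExperimentDesign("pop_chamber", [spec], seed=5, probe_max_o2=625.0)
    pop = syn.generate_pop_experiment(design)
    assert (pop["O2_diss_end"] == 625.0).all()
    assert pop["diss_lower_bound"].all()


# ---------------------------------------------------------------------------
# cell sizes

def test_unit_aspect_cells_are_spheres():
    spec = TreatmentSpec(
        "spheres", "control",
        mean_map={"volume_median": 0.2, "volume_sigma_log": 0.0,
                  "aspect_mean": 1.0, "aspect_sd": 0.0},
        n_replicates=5,
    )
    df = syn.generate_cell_sizes(ExperimentDesign("cell_sizes", [spec], seed=1))
    assert np.allclose(df["length_um"], df["width_um"])
    assert np.allclose(df["volume_um3"], np.pi * df["width_um"] ** 3 / 6)


def test_volume_median_near_configured(cell_design):
    big = syn.default_cell_size_design(seed=2, n_cells=10_000)
    df = syn.generate_cell_sizes(big)
    med = df[df["treatment"] == "control"]["volume_um3"].median()
    assert 0.09 <= med <= 0.11


def test_physical_bounds_hold_everywhere(dark_design, pop_design, tank_design, cell_design):
    dark = syn.generate_dark_incubation(dark_design)
    conc = dark[["DOC_start", "DOC_end", "O2_start", "O2_end",
                 "cells_start", "cells_end"]]
    assert (conc >= 0).all().all()
    assert (dark["DOC_end"] <= dark["DOC_start"] + 1e-12).all()
    pop = syn.generate_pop_experiment(pop_design)
    assert (pop["gas_volume"] >= 0).all()
    assert pop["gas_O2_fraction"].between(0, 1).all()
    counts, diam = syn.generate_open_tank(tank_design)
    assert (counts["count"] >= 0).all()
    assert (diam["diameter_mm"] > 0).all()
    cells = syn.generate_cell_sizes(cell_design)
    assert (cells["width_um"] > 0).all()
    assert (cells["length_um"] >= cells["width_um"] - 1e-12).all()


# ---------------------------------------------------------------------------
# validation errors

def test_validation_errors():
    with pytest.raises(ValueError, match="negative sd"):
        TreatmentSpec("x", "fleshy", {"DOC_start": 1.0}, {"DOC_start": -1.0})
    with pytest.raises(ValueError, match="sd_map keys"):
        TreatmentSpec("x", "fleshy", {"DOC_start": 1.0}, {"nope": 1.0})
    with pytest.raises(ValueError, match="group"):
        TreatmentSpec("x", "weird", {"DOC_start": 1.0})
    with pytest.raises(ValueError, match="unknown quantities"):
        spec = TreatmentSpec("x", "fleshy", {"DOC_start": 1.0, "volume_median": 1.0})
        ExperimentDesign("dark_incubation", [spec]).validate_quantities()
    with pytest.raises(ValueError, match="duration"):
        ExperimentDesign("dark_incubation", [], duration=0.0)
    spec = TreatmentSpec(
        "x", "fleshy",
        mean_map={"bubbles_per_min_per_dm2": 1.0, "bubble_diameter_mean": -0.5,
                  "bubble_diameter_sd": 0.1, "surface_area_dm2": 1.0,
                  "duration_min": 10.0},
    )
    with pytest.raises(ValueError, match="diameter"):
        syn.generate_open_tank(ExperimentDesign("open_tank", [spec], seed=1))
    spec = TreatmentSpec(
        "x", "fleshy",
        mean_map={"surface_area": 10.0, "O2_diss_start": 200.0,
                  "O2_diss_end": 210.0, "gas_volume": 1.0,
                  "gas_O2_fraction": 1.5},
    )
    with pytest.raises(ValueError, match="fraction"):
        syn.generate_pop_experiment(ExperimentDesign("pop_chamber", [spec], seed=1))
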