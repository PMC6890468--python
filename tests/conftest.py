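import dataclasses

import pytest

from reefbudget import synthetic as syn


def zero_noise(design: syn.ExperimentDesign) -> syn.ExperimentDesign:
    """Copy of a design with every replicate-level sd set to zero."""
    treatments = [
        dataclasses.replace(t, sd_map={k: 0.0 for k in t.sd_map})
        for t in design.treatments
    ]
    return dataclasses.replace(design, treatments=treatments)


@pytest.fixture
def dark_design():
    return syn.default_dark_design(seed=11)


@pytest.fixture
def pop_design():
    return syn.default_pop_design(seed=11)


@pytest.fixture
def tank_design():
    return syn.default_open_tank_design(seed=11)


@pytest.fixture
def cell_design():
    return syn.default_cell_size_design(seed=11, n_cells=200)
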