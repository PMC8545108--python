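import logging

import numpy as np
import pandas as pd
import pytest

from domthermo import msio
from domthermo.synthetic_data import (
    SynthesisConfig,
    generate_formula_library,
    generate_peak_lists,
    generate_soil_and_thermo_structure,
)

logging.getLogger("domthermo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg() -> SynthesisConfig:
    """A reduced study: 6 sites x 9 samples but a compact formula library."""
    return SynthesisConfig(seed=11, n_formulas=120, n_taxa=120,
                           n_cluster1=20, n_cluster2=20, singleton_fraction=0.2)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """(library, soil, peak_lists, blanks, truth) generated once per session."""
    library = generate_formula_library(small_cfg)
    soil = generate_soil_and_thermo_structure(small_cfg)
    peak_lists, blanks, truth = generate_peak_lists(library, small_cfg, soil)
    return library, soil, peak_lists, blanks, truth


def make_peak_list(sample_id, rows):
    return msio.PeakList(
        sample_id, [msio.Peak(mz=m, intensity=i, sn=s) for m, i, s in rows]
    )


@pytest.fixture
def peak_list_factory():
    return make_peak_list
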