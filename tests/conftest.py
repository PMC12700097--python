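import numpy as np
import pandas as pd
import pytest

import fluidmix as fm
from fluidmix.simdata import make_population_panel


@pytest.fixture(scope="session")
def profiles_small():
    return fm.make_fluid_profiles(
        n_genes=200, n_markers_per_fluid=8, marker_fold=8.0, seed=11
    )


@pytest.fixture(scope="session")
def reference_small(profiles_small):
    return fm.simulate_reference_samples(
        profiles_small, n_reps=4, library_size=2e5, seed=12
    )


@pytest.fixture(scope="session")
def panel_small():
    return make_population_panel(
        n_snps=300, n_pops=5, n_individuals=60, fst=0.1, seed=13
    )


@pytest.fixture(scope="session")
def balanced_bundle():
    """Two-fluid balanced mixtures with variant calls and truth genotypes."""
    designs = [
        d
        for d in fm.make_design_grid("two_person_subset")
        if abs(d.fractions[d.fluids[0]] - 0.5) < 1e-9
    ]
    return fm.make_bundle(
        designs, seed=7, with_variants=True, depth_scale=190_000.0
    )


@pytest.fixture(scope="session")
def de_tables_small(reference_small):
    from fluidmix.markers import pairwise_de_tables

    return pairwise_de_tables(reference_small, sorted(reference_small.fluids.unique()))
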