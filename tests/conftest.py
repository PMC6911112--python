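import numpy as np
import pandas as pd
import pytest

import exploradapt as ea


@pytest.fixture(scope="session")
def demo_data():
    """Desk-scale synthetic study: 300 genes, 20 pathways, 3 locations."""
    spec = ea.demo_spec(seed=1)
    network, pmap, cohort = ea.generate_all(spec)
    return spec, network, pmap, cohort


@pytest.fixture(scope="session")
def demo_context(demo_data):
    _, network, pmap, cohort = demo_data
    return ea.SimulationContext(cohort, network, pmap)


@pytest.fixture(scope="session")
def demo_phenotypes(demo_data):
    _, _, pmap, cohort = demo_data
    return ea.cohort_phenotypes(cohort, pmap)


@pytest.fixture(scope="session")
def asymmetric_context():
    """Heterogeneous source A (wide bands) vs homogeneous shifted target B."""
    from exploradapt.synthetic import asymmetric_spec

    network, pmap, cohort = ea.generate_all(asymmetric_spec(seed=3))
    return ea.SimulationContext(cohort, network, pmap)


@pytest.fixture(scope="session")
def tiny_system():
    """Very small regulatory system for step-by-step dynamics checks."""
    spec = ea.SyntheticSpec(
        n_genes=40,
        n_tfs=10,
        target_avg_degree=3.0,
        n_pathways=5,
        pathway_size_range=(4, 8),
        overlap_fraction=0.25,
        locations=[
            ea.LocationSpec("src", 10, {}, noise_sd=1.0),
            ea.LocationSpec("tgt", 10, {"PW000": 2.0, "PW001": 2.0}, noise_sd=1.0),
        ],
        seed=7,
    )
    network, pmap, cohort = ea.generate_all(spec)
    ctx = ea.SimulationContext(cohort, network, pmap)
    return spec, network, pmap, cohort, ctx


@pytest.fixture
def toy_expression():
    return pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4", "g5"])
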