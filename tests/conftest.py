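import networkx as nx
import numpy as np
import pytest

import pathprog as pp


@pytest.fixture(scope="session")
def small_spec() -> pp.SimulationSpec:
    """A small simulated study: 200-gene interactome, 8 pathways, two planted
    prognostic crosstalk features, 120 patients."""
    return pp.SimulationSpec(
        n_genes=200,
        n_pathways=8,
        n_patients=120,
        pathway_size_range=(12, 20),
        planted_features=("P1-P2", "P3-P4"),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    network = pp.generate_network(small_spec)
    pathways = pp.generate_pathways(small_spec, network)
    cohort, truth = pp.generate_cohort(small_spec, network, pathways)
    return network, pathways, cohort, truth


@pytest.fixture(scope="session")
def small_matrix(small_spec, small_dataset):
    """Feature matrix for the small study (40 null rewirings)."""
    network, pathways, cohort, _ = small_dataset
    config = pp.PropagationConfig(n_null=40, rng_seed=small_spec.rng_seed)
    matrix, catalogue = pp.build_feature_matrix(cohort, network, pathways, config)
    return matrix, catalogue


@pytest.fixture()
def toy_network() -> nx.Graph:
    #    a - b - c
    #        |
    #        d - e     f - g   (two components)
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("b", "d"), ("d", "e"), ("f", "g")])
    return g


@pytest.fixture()
def toy_pathways() -> pp.PathwayCollection:
    return pp.PathwayCollection(
        ids=("P1", "P2", "P3"),
        names=("one", "two", "three"),
        gene_sets=(
            frozenset({"a", "b", "c"}),
            frozenset({"b", "c", "d"}),
            frozenset({"f", "g"}),
        ),
    )
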