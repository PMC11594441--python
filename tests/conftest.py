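from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from herbwalk import (
    HerbCatalog,
    MultiscaleNetwork,
    SyntheticConfig,
    generate_study,
    write_study,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def tiny_net() -> MultiscaleNetwork:
    """Three proteins, two functions, one edge in every layer class."""
    return MultiscaleNetwork.from_edges(
        ppi=[("A", "B"), ("B", "C")],
        annotations=[("A", "F1"), ("C", "F2")],
        hierarchy=[("F1", "F2")],
    )


@pytest.fixture
def tiny_catalog() -> HerbCatalog:
    return HerbCatalog.from_pairs(
        herb_ingredient=[
            ("H1", "i1"),
            ("H1", "i2"),
            ("H1", "i3"),
            ("H2", "i4"),
            ("H2", "i5"),
        ],
        ingredient_target=[
            ("i1", "P1"),
            ("i1", "P2"),
            ("i2", "P2"),
            ("i3", "P3"),
            ("i4", "P1"),
        ],
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study reused across pipeline-level tests.

    The planted signal is deliberately strong (targets drawn from the
    disease module itself, many targeted ingredients per herb) so that the
    prioritization gates — overlap significance, >=5-fold enrichment, >=5
    significant ingredients — can all fire at this small scale.
    """
    config = SyntheticConfig(
        n_proteins=300,
        n_functions=60,
        n_herbs=15,
        disease_module_size=12,
        ingredients_per_herb=(5, 8),
        targets_per_ingredient=(2, 6),
        proximity_hops=0,
        rng_seed=7,
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, small_study):
    """The same study serialized in the on-disk formats the pipeline reads."""
    net, disease, catalog, truth = small_study
    out = tmp_path_factory.mktemp("study")
    paths = write_study(out, net, disease, catalog, truth)
    return paths


def random_multiscale_network(rng: np.random.Generator, max_nodes: int = 50):
    """A small random three-layer network, possibly with isolated nodes."""
    n_p = int(rng.integers(2, max(3, int(max_nodes * 0.7))))
    n_f = int(rng.integers(1, max(2, max_nodes - n_p)))
    proteins = [f"P{i:02d}" for i in range(n_p)]
    functions = [f"F{i:02d}" for i in range(n_f)]
    ppi = [
        (proteins[i], proteins[j])
        for i in range(n_p)
        for j in range(i + 1, n_p)
        if rng.random() < 0.15
    ]
    annotations = [
        (p, f) for p in proteins for f in functions if rng.random() < 0.1
    ]
    hierarchy = [
        (functions[i], functions[j])
        for i in range(n_f)
        for j in range(n_f)
        if i != j and rng.random() < 0.1
    ]
    return MultiscaleNetwork.from_edges(
        ppi,
        annotations,
        hierarchy,
        extra_proteins=proteins,
        extra_functions=functions,
    )
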