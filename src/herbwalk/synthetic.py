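"""Seeded generators for synthetic interactomes, disease modules and herb
catalogs with planted effective herbs.

The generator emulates the statistical shape of the real inputs without any
of their content: a scale-free PPI layer (preferential attachment, so that
hub effects on the walk are represented), a rooted function hierarchy with
cross-links, sparse protein–function annotations, and a catalog of herbs
whose ingredients each hit a handful of protein targets. A configured
fraction of herbs is *planted*: their ingredients draw targets from the
graph neighborhood of a connected disease module (with a little uniform
leakage so recovery is nontrivial), while background herbs draw targets
uniformly. The planted/background labels are returned as ground truth so
the whole prioritization pipeline can be evaluated against a known answer.

Everything is bit-reproducible for a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .catalog import HerbCatalog, write_catalog
from .network import MultiscaleNetwork, write_network
from .prioritize import DiseaseContext
from .enrich import GeneSetLibrary, write_gmt


class ConfigError(ValueError):
    """The synthetic configuration is infeasible."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults define the standard study conditions.

    ``ingredients_per_herb`` and ``targets_per_ingredient`` are inclusive
    integer ranges sampled uniformly per herb / ingredient.
    """

    n_proteins: int = 800
    n_functions: int = 300
    ppi_attachment: int = 3
    annotation_density: float = 2.0
    hierarchy_branching: int = 3
    disease_module_size: int = 15
    n_herbs: int = 60
    ingredients_per_herb: tuple[int, int] = (3, 8)
    targets_per_ingredient: tuple[int, int] = (1, 6)
    planted_fraction: float = 0.2
    proximity_hops: int = 1
    leakage: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.n_proteins,
            self.n_functions,
            self.ppi_attachment,
            self.hierarchy_branching,
            self.disease_module_size,
            self.n_herbs,
        )
        if any(v < 1 for v in positive):
            raise ConfigError("all counts must be positive")
        if self.ppi_attachment >= self.n_proteins:
            raise ConfigError("ppi_attachment must be < n_proteins")
        if self.disease_module_size > self.n_proteins:
            raise ConfigError("disease module larger than proteome")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ConfigError("planted_fraction must be in [0, 1]")
        if not (0.0 <= self.leakage <= 1.0):
            raise ConfigError("leakage must be in [0, 1]")
        for lo, hi in (self.ingredients_per_herb, self.targets_per_ingredient):
            if lo < 1 or hi < lo:
                raise ConfigError("ranges must satisfy 1 <= lo <= hi")
        if self.annotation_density < 0:
            raise ConfigError("annotation_density must be nonnegative")
        if self.proximity_hops < 0:
            raise ConfigError("proximity_hops must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    planted_herbs: frozenset[str]
    disease_proteins: frozenset[str]


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def _function_id(i: int) -> str:
    return f"F{i:04d}"


def generate_network(config: SyntheticConfig) -> MultiscaleNetwork:
    """Generate the three-layer interactome for ``config``.

    PPI: Barabási–Albert preferential attachment (connected for m >= 1).
    Hierarchy: each function i > 0 attaches to a parent drawn from the first
    ``ceil(i / branching)`` functions, which yields roughly ``branching``
    children per internal node, plus ~25% extra child→ancestor cross-links.
    Annotations: ``annotation_density * n_proteins`` random protein–function
    pairs without duplicates.
    """
    rng = np.random.default_rng(config.rng_seed)

    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(config.n_proteins, config.ppi_attachment, seed=ba_seed)
    ppi = [(_protein_id(a), _protein_id(b)) for a, b in sorted(g.edges())]

    hierarchy: list[tuple[str, str]] = []
    for i in range(1, config.n_functions):
        pool = max(1, -(-i // config.hierarchy_branching))  # ceil division
        parent = int(rng.integers(0, pool))
        hierarchy.append((_function_id(i), _function_id(parent)))
    n_cross = config.n_functions // 4
    for _ in range(n_cross):
        child = int(rng.integers(1, config.n_functions))
        parent = int(rng.integers(0, child))
        edge = (_function_id(child), _function_id(parent))
        if edge not in hierarchy:
            hierarchy.append(edge)

    n_annotations = int(round(config.annotation_density * config.n_proteins))
    seen: set[tuple[str, str]] = set()
    annotations: list[tuple[str, str]] = []
    while len(annotations) < n_annotations:
        p = _protein_id(int(rng.integers(0, config.n_proteins)))
        f = _function_id(int(rng.integers(0, config.n_functions)))
        if (p, f) not in seen:
            seen.add((p, f))
            annotations.append((p, f))

    return MultiscaleNetwork.from_edges(
        ppi=ppi,
        annotations=annotations,
        hierarchy=hierarchy,
        extra_proteins=[_protein_id(i) for i in range(config.n_proteins)],
        extra_functions=[_function_id(i) for i in range(config.n_functions)],
    )


def _disease_module(
    ppi_graph: nx.Graph, size: int, rng: np.random.Generator
) -> frozenset[str]:
    """A connected protein set grown breadth-first from a random start."""
    start = sorted(ppi_graph.nodes)[int(rng.integers(0, ppi_graph.number_of_nodes()))]
    module = [start]
    member = {start}
    frontier = sorted(ppi_graph.neighbors(start))
    while len(module) < size and frontier:
        nxt = frontier[int(rng.integers(0, len(frontier)))]
        member.add(nxt)
        module.append(nxt)
        frontier = sorted(
            {nb for m in module for nb in ppi_graph.neighbors(m)} - member
        )
    return frozenset(module)


def _neighborhood(
    ppi_graph: nx.Graph, module: frozenset[str], hops: int
) -> list[str]:
    """Proteins within ``hops`` PPI steps of the module (module included)."""
    current = set(module)
    for _ in range(hops):
        current |= {nb for n in current for nb in ppi_graph.neighbors(n)}
    return sorted(current)


def generate_study(
    config: SyntheticConfig,
) -> tuple[MultiscaleNetwork, DiseaseContext, HerbCatalog, GroundTruth]:
    """Generate network, disease context, herb catalog, and ground truth.

    Planted herbs draw each ingredient target from the disease-module
    neighborhood with probability ``1 - leakage`` (uniform elsewhere
    otherwise); the first target of each planted herb is forced into the
    neighborhood so every planted herb touches it. Background herbs draw
    uniformly over all proteins.
    """
    net = generate_network(config)
    rng = np.random.default_rng(config.rng_seed + 1)

    ppi_graph = nx.Graph()
    ppi_graph.add_nodes_from(sorted(net.proteins))
    for e in net.edges_by_layer("ppi"):
        ppi_graph.add_edge(e.source, e.target)

    module = _disease_module(ppi_graph, config.disease_module_size, rng)
    neighborhood = _neighborhood(ppi_graph, module, config.proximity_hops)
    all_proteins = sorted(net.proteins)

    n_planted = int(round(config.planted_fraction * config.n_herbs))
    herb_ids = [f"HERB{i:03d}" for i in range(config.n_herbs)]
    planted = frozenset(
        herb_ids[i]
        for i in rng.choice(config.n_herbs, size=n_planted, replace=False)
    )

    herb_ingredient: list[tuple[str, str]] = []
    ingredient_target: list[tuple[str, str]] = []
    lo_i, hi_i = config.ingredients_per_herb
    lo_t, hi_t = config.targets_per_ingredient
    for herb in herb_ids:
        is_planted = herb in planted
        n_ing = int(rng.integers(lo_i, hi_i + 1))
        first_of_herb = True
        for j in range(n_ing):
            ing = f"{herb}:ING{j:02d}"
            herb_ingredient.append((herb, ing))
            n_t = int(rng.integers(lo_t, hi_t + 1))
            targets: set[str] = set()
            while len(targets) < n_t:
                if is_planted and (
                    first_of_herb or rng.random() >= config.leakage
                ):
                    pool = neighborhood
                else:
                    pool = all_proteins
                targets.add(pool[int(rng.integers(0, len(pool)))])
                first_of_herb = False
            for t in sorted(targets):
                ingredient_target.append((ing, t))

    catalog = HerbCatalog.from_pairs(herb_ingredient, ingredient_target)
    disease = DiseaseContext(
        disease_id="SYNTHETIC_DISEASE",
        disease_proteins=module,
        population_size=len(net.proteins),
    )
    truth = GroundTruth(planted_herbs=planted, disease_proteins=module)
    return net, disease, catalog, truth


def annotation_library(net: MultiscaleNetwork, min_size: int = 3) -> GeneSetLibrary:
    """A gene-set library derived from the annotation layer: one term per
    function with at least ``min_size`` annotated proteins."""
    sets: dict[str, frozenset[str]] = {}
    for f in sorted(net.functions):
        genes = frozenset(
            nb for nb, cls in net.neighbors(f) if cls == "fp"
        )
        if len(genes) >= min_size:
            sets[f] = genes
    return GeneSetLibrary(sets, source="synthetic-annotations")


def write_study(
    out_dir: str | Path,
    net: MultiscaleNetwork,
    disease: DiseaseContext,
    catalog: HerbCatalog,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write a study in the TSV/GMT formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out / "ppi.tsv",
        "annotation": out / "annotation.tsv",
        "hierarchy": out / "hierarchy.tsv",
        "herb_ingredient": out / "herb_ingredient.tsv",
        "ingredient_target": out / "ingredient_target.tsv",
        "disease_proteins": out / "disease_proteins.txt",
        "library": out / "annotation_library.gmt",
    }
    write_network(net, paths["ppi"], paths["annotation"], paths["hierarchy"])
    write_catalog(catalog, paths["herb_ingredient"], paths["ingredient_target"])
    paths["disease_proteins"].write_text(
        "\n".join(sorted(disease.disease_proteins)) + "\n"
    )
    write_gmt(annotation_library(net), paths["library"])
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.tsv"
        with paths["ground_truth"].open("w") as fh:
            for herb in sorted(truth.planted_herbs):
                fh.write(f"{herb}\tplanted\n")
    return paths
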