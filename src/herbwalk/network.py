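"""Three-layer multiscale interactome: proteins, biological functions, and the
edges that connect them.

The network couples two node classes — proteins and biological functions —
through three edge layers:

* ``ppi``        protein–protein physical interactions (undirected),
* ``annotation`` protein–function associations (undirected),
* ``hierarchy``  function–function parent/child links, stored as
  (child, parent) and traversable both up and down.

A random walk on this substrate (see :mod:`herbwalk.diffusion`) distinguishes
five move classes derived from the three layers: protein→protein,
protein→function, function→protein, function→parent and function→child.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("herbwalk.network")

PROTEIN = "protein"
FUNCTION = "function"

PPI = "ppi"
ANNOTATION = "annotation"
HIERARCHY = "hierarchy"
LAYERS = (PPI, ANNOTATION, HIERARCHY)

# Walk move classes (edge classes seen from a walker standing on a node).
PP = "pp"        # protein -> protein        (ppi)
PF = "pf"        # protein -> function       (annotation)
FP = "fp"        # function -> protein       (annotation)
UP = "up"        # function -> parent fn     (hierarchy, child side)
DOWN = "down"    # function -> child fn      (hierarchy, parent side)


class NetworkValidationError(ValueError):
    """A structural rule of the multiscale network was violated."""


class EdgeFileError(ValueError):
    """An input edge-list file is malformed."""


@dataclass(frozen=True)
class Node:
    """A network node: an opaque id plus its class (protein or function)."""

    id: str
    kind: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (PROTEIN, FUNCTION):
            raise NetworkValidationError(f"unknown node kind {self.kind!r}")


@dataclass(frozen=True, order=True)
class TypedEdge:
    """A canonicalized edge: (source, target) within one of the three layers.

    ``ppi`` edges are stored with lexicographically sorted endpoints,
    ``annotation`` edges as (protein, function), ``hierarchy`` edges as
    (child, parent).
    """

    source: str
    target: str
    layer: str


def _read_edge_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2+-column TSV edge list, skipping blanks and ``#`` comments.

    Extra columns are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeFileError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    return rows


class MultiscaleNetwork:
    """Validated, canonicalized container for the three edge layers.

    Exposes a per-node adjacency index keyed by walk move class, which is the
    only view the diffusion code needs.
    """

    def __init__(
        self,
        proteins: Iterable[str],
        functions: Iterable[str],
        edges: Iterable[TypedEdge],
    ) -> None:
        self.proteins: frozenset[str] = frozenset(proteins)
        self.functions: frozenset[str] = frozenset(functions)
        overlap = self.proteins & self.functions
        if overlap:
            raise NetworkValidationError(
                f"ids declared as both protein and function: {sorted(overlap)}"
            )
        self._edges: frozenset[TypedEdge] = frozenset(
            self._canonicalize(e) for e in edges
        )
        self._validate_edges()
        self._adjacency = self._build_adjacency()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        ppi: Iterable[tuple[str, str]],
        annotations: Iterable[tuple[str, str]],
        hierarchy: Iterable[tuple[str, str]],
        extra_proteins: Iterable[str] = (),
        extra_functions: Iterable[str] = (),
    ) -> "MultiscaleNetwork":
        """Build from raw pair lists.

        ``annotations`` rows are (protein, function); ``hierarchy`` rows are
        (child, parent). Node kinds are inferred from layer membership; an id
        implied to be both a protein and a function raises
        :class:`NetworkValidationError` naming the id.
        """
        ppi = list(ppi)
        annotations = list(annotations)
        hierarchy = list(hierarchy)
        proteins: set[str] = set(extra_proteins)
        functions: set[str] = set(extra_functions)
        for a, b in ppi:
            proteins.update((a, b))
        for p, f in annotations:
            proteins.add(p)
            functions.add(f)
        for c, p in hierarchy:
            functions.update((c, p))

        n_self = 0
        edges: list[TypedEdge] = []
        for a, b in ppi:
            if a == b:
                n_self += 1
                continue
            edges.append(TypedEdge(min(a, b), max(a, b), PPI))
        for p, f in annotations:
            if p == f:
                n_self += 1
                continue
            edges.append(TypedEdge(p, f, ANNOTATION))
        for c, p in hierarchy:
            if c == p:
                n_self += 1
                continue
            edges.append(TypedEdge(c, p, HIERARCHY))
        if n_self:
            logger.info("dropped %d self-loop edges", n_self)
        return cls(proteins, functions, edges)

    def _canonicalize(self, edge: TypedEdge) -> TypedEdge:
        if edge.layer not in LAYERS:
            raise NetworkValidationError(f"unknown layer {edge.layer!r}")
        if edge.source == edge.target:
            raise NetworkValidationError(f"self-loop on {edge.source!r}")
        if edge.layer == PPI and edge.source > edge.target:
            return TypedEdge(edge.target, edge.source, PPI)
        return edge

    def _validate_edges(self) -> None:
        nodes = self.proteins | self.functions
        for e in self._edges:
            for endpoint in (e.source, e.target):
                if endpoint not in nodes:
                    raise NetworkValidationError(
                        f"edge endpoint {endpoint!r} not declared as a node"
                    )
            if e.layer == PPI:
                ok = e.source in self.proteins and e.target in self.proteins
            elif e.layer == ANNOTATION:
                ok = e.source in self.proteins and e.target in self.functions
            else:
                ok = e.source in self.functions and e.target in self.functions
            if not ok:
                raise NetworkValidationError(
                    f"edge ({e.source}, {e.target}) violates the endpoint "
                    f"rule of layer {e.layer!r}"
                )

    def _build_adjacency(self) -> dict[str, list[tuple[str, str]]]:
        adj: dict[str, list[tuple[str, str]]] = {
            n: [] for n in self.proteins | self.functions
        }
        for e in self._edges:
            if e.layer == PPI:
                adj[e.source].append((e.target, PP))
                adj[e.target].append((e.source, PP))
            elif e.layer == ANNOTATION:
                adj[e.source].append((e.target, PF))
                adj[e.target].append((e.source, FP))
            else:  # hierarchy: source=child, target=parent
                adj[e.source].append((e.target, UP))
                adj[e.target].append((e.source, DOWN))
        for n in adj:
            adj[n].sort()
        return adj

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return self.proteins | self.functions

    @property
    def edges(self) -> frozenset[TypedEdge]:
        return self._edges

    def node_kind(self, node_id: str) -> str:
        if node_id in self.proteins:
            return PROTEIN
        if node_id in self.functions:
            return FUNCTION
        raise KeyError(node_id)

    def neighbors(self, node_id: str) -> list[tuple[str, str]]:
        """Sorted (neighbor, move-class) pairs for a node."""
        return list(self._adjacency[node_id])

    def edges_by_layer(self, layer: str) -> list[TypedEdge]:
        if layer not in LAYERS:
            raise KeyError(layer)
        return sorted(e for e in self._edges if e.layer == layer)

    def degree_multiset(self) -> list[int]:
        return sorted(len(v) for v in self._adjacency.values())

    def isolated_nodes(self) -> list[str]:
        """Nodes with no incident edge in any layer (legal, but flagged)."""
        return sorted(n for n, v in self._adjacency.items() if not v)

    def summarize(self) -> dict[str, int]:
        """Cardinality summary: node counts and edge counts per layer."""
        return {
            "proteins": len(self.proteins),
            "functions": len(self.functions),
            "ppi": sum(1 for e in self._edges if e.layer == PPI),
            "annotation": sum(1 for e in self._edges if e.layer == ANNOTATION),
            "hierarchy": sum(1 for e in self._edges if e.layer == HIERARCHY),
        }

    def validation_report(self) -> str:
        lines = ["multiscale network validation"]
        for key, value in self.summarize().items():
            lines.append(f"  {key}: {value}")
        isolated = self.isolated_nodes()
        lines.append(f"  isolated nodes: {len(isolated)}")
        for n in isolated:
            lines.append(f"    isolated: {n}")
        return "\n".join(lines)


def load_network(
    ppi_path: str | Path,
    annotation_path: str | Path,
    hierarchy_path: str | Path,
) -> MultiscaleNetwork:
    """Load the three edge-list TSVs into a validated network.

    Duplicate rows (in either orientation for undirected layers) collapse to a
    single stored edge; self-loops are dropped and counted in the log.
    """
    return MultiscaleNetwork.from_edges(
        ppi=_read_edge_tsv(ppi_path),
        annotations=_read_edge_tsv(annotation_path),
        hierarchy=_read_edge_tsv(hierarchy_path),
    )


def write_network(
    net: MultiscaleNetwork,
    ppi_path: str | Path,
    annotation_path: str | Path,
    hierarchy_path: str | Path,
) -> None:
    """Re-export the canonicalized edge lists, sorted, one layer per file."""
    for layer, path in (
        (PPI, ppi_path),
        (ANNOTATION, annotation_path),
        (HIERARCHY, hierarchy_path),
    ):
        with Path(path).open("w") as fh:
            for e in net.edges_by_layer(layer):
                fh.write(f"{e.source}\t{e.target}\n")


def summarize(net: MultiscaleNetwork) -> dict[str, int]:
    """Module-level alias for :meth:`MultiscaleNetwork.summarize`."""
    return net.summarize()
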