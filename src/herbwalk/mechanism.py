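"""Mechanism-subnetwork extraction for an ingredient–disease pair.

The most influential nodes of the ingredient's and the disease's diffusion
profiles (top k of each, k = 20 by default) are collected together with the
ingredient's direct targets and the disease proteins appearing among them.
Ingredient targets that cannot reach any disease protein or any selected
biological function inside the induced subgraph are pruned — they carry no
plausible mechanistic route. Two pseudo-nodes, the ingredient and the
disease, anchor the figure topology without ever participating in the walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .diffusion import DiffusionProfile, SeedSet
from .network import MultiscaleNetwork, PPI, ANNOTATION, HIERARCHY
from .prioritize import DiseaseContext

INGREDIENT_LINK = "targets"
DISEASE_LINK = "disease_protein"

ROLE_INGREDIENT = "ingredient"
ROLE_DISEASE = "disease"
ROLE_PROTEIN = "protein"
ROLE_FUNCTION = "function"


@dataclass(frozen=True)
class SubnetworkParameters:
    """k controls how many top profile nodes each side contributes."""

    k: int = 20
    include_direct_targets: bool = True
    association: str = "reachability"  # or "adjacency"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.association not in ("reachability", "adjacency"):
            raise ValueError("association must be 'reachability' or 'adjacency'")


@dataclass
class MechanismSubnetwork:
    """Induced mechanism graph with role/frequency annotations per node."""

    graph: nx.Graph
    ingredient_node: str
    disease_node: str

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def real_nodes(self) -> set[str]:
        return self.nodes - {self.ingredient_node, self.disease_node}

    def node_table(self) -> list[dict]:
        rows = []
        for n in sorted(self.graph.nodes):
            d = self.graph.nodes[n]
            rows.append(
                {
                    "node": n,
                    "role": d.get("role", ""),
                    "frequency": d.get("frequency", 0.0),
                    "rank": d.get("rank", ""),
                    "source_profile": d.get("source_profile", ""),
                }
            )
        return rows


def top_k_entities(
    profile: DiffusionProfile, k: int, exclude: frozenset[str] | set[str] = frozenset()
) -> list[str]:
    """The k nodes with highest visitation frequency, ties by id ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(
        ((n, f) for n, f in profile.frequencies.items() if n not in exclude),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return [n for n, _ in ordered[:k]]


def build_subnetwork(
    net: MultiscaleNetwork,
    ingredient_targets: SeedSet,
    disease: DiseaseContext,
    profile_ing: DiffusionProfile,
    profile_dis: DiffusionProfile,
    params: SubnetworkParameters = SubnetworkParameters(),
    *,
    ingredient_id: str = "INGREDIENT",
) -> MechanismSubnetwork:
    """Assemble the mechanism subnetwork for one ingredient–disease pair.

    Node selection: top-k of each profile, plus direct ingredient targets
    (optional) and disease proteins already among the selected nodes. Direct
    targets with no route (path within the induced subgraph, or direct
    adjacency when configured) to a disease protein or selected function are
    excluded. Edges are those of the parent network induced on the final
    node set, plus ingredient→target and disease→disease-protein links.
    """
    topk_ing = top_k_entities(profile_ing, params.k)
    topk_dis = top_k_entities(profile_dis, params.k)
    direct = sorted(set(ingredient_targets.ids()) & net.nodes)

    selected: set[str] = set(topk_ing) | set(topk_dis)
    if params.include_direct_targets:
        selected |= set(direct)
    selected |= disease.disease_proteins & (set(topk_ing) | set(topk_dis))

    induced = nx.Graph()
    induced.add_nodes_from(selected)
    for e in net.edges:
        if e.source in selected and e.target in selected:
            induced.add_edge(e.source, e.target, layer=e.layer)

    goals = (disease.disease_proteins & selected) | {
        n for n in selected if n in net.functions
    }
    to_remove: set[str] = set()
    for t in direct:
        if t not in selected or t in goals:
            continue
        if params.association == "adjacency":
            connected = any(nb in goals for nb in induced.neighbors(t))
        else:
            reachable = nx.node_connected_component(induced, t)
            connected = bool(reachable & goals)
        if not connected:
            to_remove.add(t)
    final_nodes = selected - to_remove
    if not final_nodes:
        raise ValueError("mechanism subnetwork is empty")

    g = nx.Graph()
    rank_ing = {n: i + 1 for i, n in enumerate(topk_ing)}
    rank_dis = {n: i + 1 for i, n in enumerate(topk_dis)}
    for n in sorted(final_nodes):
        role = ROLE_PROTEIN if n in net.proteins else ROLE_FUNCTION
        source = []
        if n in rank_ing:
            source.append("ingredient")
        if n in rank_dis:
            source.append("disease")
        g.add_node(
            n,
            role=role,
            frequency=float(profile_ing.frequencies.get(n, 0.0)),
            disease_frequency=float(profile_dis.frequencies.get(n, 0.0)),
            rank=rank_ing.get(n, rank_dis.get(n, 0)),
            source_profile="+".join(source) or "target",
        )
    for e in net.edges:
        if e.source in final_nodes and e.target in final_nodes:
            g.add_edge(e.source, e.target, layer=e.layer)

    ing_node = f"ingredient:{ingredient_id}"
    dis_node = f"disease:{disease.disease_id}"
    g.add_node(ing_node, role=ROLE_INGREDIENT, frequency=0.0, rank=0, source_profile="")
    g.add_node(dis_node, role=ROLE_DISEASE, frequency=0.0, rank=0, source_profile="")
    for t in direct:
        if t in final_nodes:
            g.add_edge(ing_node, t, layer=INGREDIENT_LINK)
    for p in sorted(disease.disease_proteins & final_nodes):
        g.add_edge(dis_node, p, layer=DISEASE_LINK)

    return MechanismSubnetwork(g, ing_node, dis_node)


def export_subnetwork(
    sub: MechanismSubnetwork, path: str | Path, format: str = "sif"
) -> Path:
    """Write the subnetwork as SIF (``source<TAB>layer<TAB>target``) or
    GraphML (with role/frequency attributes). SIF output is byte-stable:
    edges are emitted sorted."""
    path = Path(path)
    if sub.graph.number_of_nodes() == 0:
        raise ValueError("subnetwork is empty")
    if format == "sif":
        lines = sorted(
            f"{min(u, v)}\t{d['layer']}\t{max(u, v)}"
            for u, v, d in sub.graph.edges(data=True)
        )
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        g = sub.graph.copy()
        g.graph["ingredient_node"] = sub.ingredient_node
        g.graph["disease_node"] = sub.disease_node
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_graphml(path: str | Path) -> MechanismSubnetwork:
    g = nx.read_graphml(path)
    return MechanismSubnetwork(
        nx.Graph(g), g.graph["ingredient_node"], g.graph["disease_node"]
    )
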