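"""Biased random walk with restart on the multiscale network.

The walker starts from a seed distribution s (the proteins associated with a
herb, ingredient, or disease). At each step it restarts to s with probability
alpha, otherwise it moves to a neighbor with probability proportional to the
weight of the connecting edge class. Unequal class weights bias the walk —
the defaults favor moves toward biological-function nodes, so that the
stationary distribution reflects functional context, not just local PPI
topology. The stationary distribution r, the *diffusion profile*, satisfies

    r = (1 - alpha) * T' r + alpha * s

with T the row-stochastic transition operator (mass on dangling nodes is
redirected to s). Profiles are computed by power iteration with an L1
stopping rule and are fully deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping
import json
import logging

import numpy as np
import scipy.sparse as sp

from .network import MultiscaleNetwork, PP, PF, FP, UP, DOWN

logger = logging.getLogger("herbwalk.diffusion")


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the final residual."""

    def __init__(self, residual: float, iterations: int) -> None:
        super().__init__(
            f"diffusion did not converge after {iterations} iterations "
            f"(L1 residual {residual:.3e})"
        )
        self.residual = residual
        self.iterations = iterations


class EmptySeedError(ValueError):
    """Seed set is disjoint from the network; lists the dropped ids."""


@dataclass(frozen=True)
class WalkParameters:
    """Restart probability, per-edge-class weights, and iteration controls.

    Defaults realize the intended bias toward biological functions: moves
    entering or ascending the function layer (``w_pf``, ``w_up``) carry twice
    the weight of protein-level moves.
    """

    restart_probability: float = 0.17
    w_pp: float = 1.0
    w_pf: float = 2.0
    w_fp: float = 1.0
    w_up: float = 2.0
    w_down: float = 1.0
    tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_probability <= 1.0):
            raise ValueError("restart_probability must be in (0, 1]")
        weights = (self.w_pp, self.w_pf, self.w_fp, self.w_up, self.w_down)
        if any(w < 0 for w in weights):
            raise ValueError("edge-class weights must be nonnegative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one edge-class weight must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")

    def weight(self, move_class: str) -> float:
        return {
            PP: self.w_pp,
            PF: self.w_pf,
            FP: self.w_fp,
            UP: self.w_up,
            DOWN: self.w_down,
        }[move_class]


class SeedSet:
    """Nonnegative node weights summing to one; uniform by default."""

    def __init__(self, weights: Mapping[str, float]) -> None:
        if not weights:
            raise EmptySeedError("seed set is empty")
        if any(w < 0 for w in weights.values()):
            raise ValueError("seed weights must be nonnegative")
        total = float(sum(weights.values()))
        if total <= 0:
            raise ValueError("seed weights must sum to a positive value")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("seed weights must sum to 1 (use SeedSet.normalized)")
        self.weights: dict[str, float] = {k: float(v) for k, v in sorted(weights.items())}

    @classmethod
    def uniform(cls, ids: Iterable[str]) -> "SeedSet":
        ids = sorted(set(ids))
        if not ids:
            raise EmptySeedError("seed set is empty")
        w = 1.0 / len(ids)
        return cls({i: w for i in ids})

    @classmethod
    def normalized(cls, weights: Mapping[str, float]) -> "SeedSet":
        total = float(sum(weights.values()))
        if total <= 0:
            raise ValueError("seed weights must sum to a positive value")
        return cls({k: v / total for k, v in weights.items()})

    def ids(self) -> list[str]:
        return list(self.weights)

    def restrict_to(self, nodes: Iterable[str]) -> "SeedSet":
        """Drop seeds outside ``nodes`` and renormalize; error if none remain."""
        nodes = set(nodes)
        kept = {k: v for k, v in self.weights.items() if k in nodes and v > 0}
        if not kept:
            raise EmptySeedError(
                "no seed overlaps the network; dropped ids: "
                + ", ".join(sorted(self.weights))
            )
        dropped = sorted(set(self.weights) - set(kept))
        if dropped:
            logger.info("seed ids outside network dropped: %s", ", ".join(dropped))
        return SeedSet.normalized(kept)


@dataclass
class DiffusionProfile:
    """Visitation frequencies over all network nodes, plus provenance."""

    frequencies: dict[str, float]
    seeds: SeedSet
    params: WalkParameters
    iterations: int
    residual: float

    def as_vector(self, order: list[str]) -> np.ndarray:
        return np.array([self.frequencies.get(n, 0.0) for n in order])

    def total_mass(self) -> float:
        return float(sum(self.frequencies.values()))


class TransitionOperator:
    """Row-stochastic sparse transition matrix over a fixed sorted node order.

    Rows of dangling nodes (no incident edge, or all incident classes
    weighted zero) are zero; their mass is redirected to the seed
    distribution during iteration.
    """

    def __init__(self, net: MultiscaleNetwork, params: WalkParameters) -> None:
        self.node_order: list[str] = sorted(net.nodes)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.node_order)}
        n = len(self.node_order)
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        dangling = np.zeros(n, dtype=bool)
        for i, u in enumerate(self.node_order):
            nbrs = net.neighbors(u)  # sorted (neighbor, class)
            # a neighbor pair can be connected through more than one class
            acc: dict[str, float] = {}
            for v, cls in nbrs:
                w = params.weight(cls)
                if w > 0:
                    acc[v] = acc.get(v, 0.0) + w
            z = sum(acc.values())
            if z <= 0:
                dangling[i] = True
                if nbrs:
                    logger.debug("node %s dangling: all incident classes weighted 0", u)
                continue
            for v in sorted(acc):
                rows.append(i)
                cols.append(self.index[v])
                vals.append(acc[v] / z)
        self.matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self.matrix_t = self.matrix.T.tocsr()
        self.dangling = dangling

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)


def build_transition_operator(
    net: MultiscaleNetwork, params: WalkParameters
) -> TransitionOperator:
    """Build the biased transition operator for ``net`` under ``params``."""
    return TransitionOperator(net, params)


def compute_diffusion_profile(
    net: MultiscaleNetwork | TransitionOperator,
    seeds: SeedSet,
    params: WalkParameters,
) -> DiffusionProfile:
    """Power-iterate the restart equation to the stationary profile.

    Accepts a prebuilt :class:`TransitionOperator` so that many profiles can
    share one operator. Mass is conserved at every iteration (dangling mass
    restarts to the seeds), so the profile sums to one.
    """
    op = net if isinstance(net, TransitionOperator) else TransitionOperator(net, params)
    seeds = seeds.restrict_to(op.node_order)
    alpha = params.restart_probability

    s = np.zeros(op.n_nodes)
    for node, w in seeds.weights.items():
        s[op.index[node]] = w

    r = s.copy()
    residual = 0.0
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        dangling_mass = float(r[op.dangling].sum()) if op.dangling.any() else 0.0
        r_new = (1.0 - alpha) * (op.matrix_t @ r)
        r_new += (alpha + (1.0 - alpha) * dangling_mass) * s
        residual = float(np.abs(r_new - r).sum())
        r = r_new
        if residual <= params.tolerance:
            break
    else:
        raise ConvergenceError(residual, params.max_iterations)

    freqs = {node: float(r[i]) for i, node in enumerate(op.node_order)}
    return DiffusionProfile(freqs, seeds, params, iterations, residual)


def top_mass_fraction(profile: DiffusionProfile, k: int) -> float:
    """Sum of the ``k`` largest visitation frequencies (ties by node id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(profile.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    return float(sum(v for _, v in ordered[:k]))


def write_profile(
    profile: DiffusionProfile,
    tsv_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Serialize as two-column TSV plus a JSON metadata sidecar."""
    with Path(tsv_path).open("w") as fh:
        for node in sorted(profile.frequencies):
            fh.write(f"{node}\t{profile.frequencies[node]:.17g}\n")
    if meta_path is not None:
        meta = {
            "seeds": profile.seeds.weights,
            "restart_probability": profile.params.restart_probability,
            "weights": {
                "pp": profile.params.w_pp,
                "pf": profile.params.w_pf,
                "fp": profile.params.w_fp,
                "up": profile.params.w_up,
                "down": profile.params.w_down,
            },
            "tolerance": profile.params.tolerance,
            "iterations": profile.iterations,
            "residual": profile.residual,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_profile(tsv_path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with Path(tsv_path).open() as fh:
        for line in fh:
            node, value = line.rstrip("\n").split("\t")
            out[node] = float(value)
    return out
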