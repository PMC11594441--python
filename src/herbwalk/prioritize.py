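"""Scoring and ranking of herbs and ingredients against a disease.

An entity (herb or ingredient) is compared to the disease along two axes:

* **correlation score** — similarity (Pearson by default) between the
  entity's diffusion profile and the disease's, over the aligned node
  universe; high similarity means the entity's influence propagates through
  the same parts of the interactome as the disease.
* **target overlap** — ``k`` of the entity's ``n`` (top-)targets are
  disease proteins; significance is the exact hypergeometric upper tail
  P(X >= k) with K disease proteins in a population of N eligible proteins,
  and the enrichment value is the fold ratio (k/n)/(K/N).

An entity is *prioritized* when its overlap p-value < 0.05, its enrichment
is at least 5, and (for herbs) at least 5 of its ingredients are themselves
significantly associated with the disease proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats

from .catalog import HerbCatalog
from .diffusion import DiffusionProfile


class UndefinedCorrelationError(ValueError):
    """A profile has zero variance, so the correlation is undefined."""


@dataclass(frozen=True)
class DiseaseContext:
    """The disease protein set and the population it is drawn from."""

    disease_id: str
    disease_proteins: frozenset[str]
    population_size: int

    def __post_init__(self) -> None:
        if len(self.disease_proteins) < 1:
            raise ValueError("disease_proteins must be nonempty")
        if self.population_size < len(self.disease_proteins):
            raise ValueError("population_size must be >= |disease_proteins|")

    @property
    def k_disease(self) -> int:
        return len(self.disease_proteins)


@dataclass(frozen=True)
class RankingRecord:
    """One row of the prioritization table."""

    entity: str
    correlation_score: float
    n_targets: int
    overlap_k: int
    hypergeom_p: float
    adjusted_p: float
    enrichment: float
    n_significant_ingredients: int | None
    prioritized: bool

    @property
    def overlap(self) -> str:
        return f"{self.overlap_k}/{self.n_targets}"


@dataclass(frozen=True)
class CoreTargetSet:
    """Proteins hit by at least ``min_herbs`` of the top-ranked herbs."""

    counts: Mapping[str, int]
    min_herbs: int

    def proteins(self) -> list[str]:
        return sorted(self.counts)


def correlation_score(
    a: DiffusionProfile | Mapping[str, float],
    b: DiffusionProfile | Mapping[str, float],
    method: str = "pearson",
    exclude: Iterable[str] = (),
) -> float:
    """Correlation between two profiles over the union of their supports.

    Nodes absent from one profile contribute frequency zero; nodes listed in
    ``exclude`` (e.g. both seed sets, when seed-masked comparison is wanted)
    are dropped before alignment.
    """
    fa = a.frequencies if isinstance(a, DiffusionProfile) else dict(a)
    fb = b.frequencies if isinstance(b, DiffusionProfile) else dict(b)
    excluded = set(exclude)
    universe = sorted((set(fa) | set(fb)) - excluded)
    if len(universe) < 2:
        raise UndefinedCorrelationError("fewer than two aligned nodes")
    x = np.array([fa.get(n, 0.0) for n in universe])
    y = np.array([fb.get(n, 0.0) for n in universe])
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero-variance profile")
    if method == "pearson":
        return float(scipy.stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(scipy.stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed with exact integer arithmetic (summed binomial products over a
    common denominator), so the result is correct to float rounding even in
    the far tail.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"infeasible counts k={k}, n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValueError(f"overlap k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    numer = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return float(Fraction(numer, comb(N, n)))


def enrichment_value(
    k: int,
    n: int,
    K: int | None = None,
    N: int | None = None,
    *,
    background_fraction: float | None = None,
) -> float:
    """Fold enrichment of the observed overlap over the background rate.

    ``(k/n) / p0`` with ``p0 = K/N``, or ``p0 = background_fraction`` when
    the population counts behind a published table are not available but the
    background rate they imply is.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0 or k > n:
        raise ValueError("require 0 <= k <= n")
    if background_fraction is not None:
        p0 = float(background_fraction)
    else:
        if K is None or N is None:
            raise ValueError("provide either (K, N) or background_fraction")
        if K < 1 or N < K:
            raise ValueError("require 1 <= K <= N")
        p0 = K / N
    if p0 <= 0:
        raise ZeroDivisionError("background fraction must be positive")
    return (k / n) / p0


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return [float(v) for v in out]


def significant_ingredient_count(
    catalog: HerbCatalog,
    herb: str,
    disease: DiseaseContext,
    p_cutoff: float = 0.05,
) -> int:
    """Number of the herb's ingredients whose own target set overlaps the
    disease proteins with hypergeometric p < ``p_cutoff``."""
    count = 0
    for ing in catalog.targeted_ingredients_of(herb):
        targets = catalog.targets_of(ing)
        k = len(set(targets) & disease.disease_proteins)
        p = hypergeometric_overlap(
            k, len(targets), disease.k_disease, disease.population_size
        )
        if p < p_cutoff:
            count += 1
    return count


def rank_entities(
    profiles: Mapping[str, DiffusionProfile],
    entity_targets: Mapping[str, Sequence[str]],
    disease: DiseaseContext,
    disease_profile: DiffusionProfile,
    *,
    method: str = "pearson",
    p_cutoff: float = 0.05,
    min_enrichment: float = 5.0,
    min_significant_ingredients: int = 5,
    significant_ingredients: Mapping[str, int] | None = None,
    exclude_seeds: bool = False,
) -> list[RankingRecord]:
    """Score every entity against the disease and sort by correlation.

    ``entity_targets`` supplies the overlap denominator for each entity: a
    herb's top-50 target list or an ingredient's full target set.
    ``significant_ingredients`` (herbs only) carries the per-herb count of
    ingredients individually associated with the disease; when omitted the
    ingredient criterion is not applied.

    Records are sorted by correlation score descending, ties by entity id
    ascending; the ordering is invariant to the input ordering of entities.
    """
    if set(profiles) != set(entity_targets):
        raise ValueError("profiles and entity_targets must cover the same entities")
    rows: list[dict] = []
    for entity in sorted(profiles):
        targets = list(entity_targets[entity])
        n = len(targets)
        k = len(set(targets) & disease.disease_proteins)
        p = hypergeometric_overlap(k, n, disease.k_disease, disease.population_size)
        enr = enrichment_value(k, n, disease.k_disease, disease.population_size)
        exclude = (
            set(profiles[entity].seeds.ids()) | set(disease_profile.seeds.ids())
            if exclude_seeds
            else set()
        )
        corr = correlation_score(
            profiles[entity], disease_profile, method=method, exclude=exclude
        )
        rows.append(
            {"entity": entity, "corr": corr, "n": n, "k": k, "p": p, "enr": enr}
        )

    adjusted = bh_adjust([row["p"] for row in rows])
    records: list[RankingRecord] = []
    for row, adj in zip(rows, adjusted):
        n_sig = (
            significant_ingredients.get(row["entity"])
            if significant_ingredients is not None
            else None
        )
        prioritized = row["p"] < p_cutoff and row["enr"] >= min_enrichment
        if significant_ingredients is not None:
            prioritized = prioritized and (n_sig or 0) >= min_significant_ingredients
        records.append(
            RankingRecord(
                entity=row["entity"],
                correlation_score=row["corr"],
                n_targets=row["n"],
                overlap_k=row["k"],
                hypergeom_p=row["p"],
                adjusted_p=adj,
                enrichment=row["enr"],
                n_significant_ingredients=n_sig,
                prioritized=prioritized,
            )
        )
    records.sort(key=lambda r: (-r.correlation_score, r.entity))
    return records


def core_targets(
    catalog: HerbCatalog,
    top_herbs: Sequence[str],
    min_herbs: int = 3,
) -> CoreTargetSet:
    """Proteins targeted (via any ingredient, full target sets) by at least
    ``min_herbs`` of ``top_herbs``, with the number of herbs hitting each."""
    unknown = sorted(set(top_herbs) - catalog.herbs)
    if unknown:
        raise KeyError(f"herbs not in catalog: {unknown}")
    counts: dict[str, int] = {}
    for herb in set(top_herbs):
        for protein in catalog.herb_targets(herb):
            counts[protein] = counts.get(protein, 0) + 1
    kept = {p: c for p, c in counts.items() if c >= min_herbs}
    return CoreTargetSet(counts=kept, min_herbs=min_herbs)
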