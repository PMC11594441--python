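"""Herb → ingredient → protein-target associations.

Herbs are multi-compound preparations; each ingredient (a chemical compound,
typically identified by a PubChem CID) may hit several protein targets, and
several ingredients of the same herb may converge on one target. The *simple
pathway count* of a target within a herb is the number of that herb's
distinct ingredients hitting it; a herb's seed proteins for diffusion are its
top targets by this count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("herbwalk.catalog")


@dataclass(frozen=True)
class TargetCount:
    """A protein target with its simple pathway count within one herb."""

    protein: str
    pathway_count: int


@dataclass(frozen=True)
class HerbCatalog:
    """Immutable association tables linking herbs, ingredients and targets."""

    herbs: frozenset[str]
    ingredients: frozenset[str]
    herb_ingredient: frozenset[tuple[str, str]]
    ingredient_target: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for h, i in self.herb_ingredient:
            if h not in self.herbs or i not in self.ingredients:
                raise ValueError(f"undeclared entity in herb_ingredient pair ({h}, {i})")
        for i, _t in self.ingredient_target:
            if i not in self.ingredients:
                raise ValueError(f"undeclared ingredient in ingredient_target: {i}")

    @classmethod
    def from_pairs(
        cls,
        herb_ingredient: Iterable[tuple[str, str]],
        ingredient_target: Iterable[tuple[str, str]],
    ) -> "HerbCatalog":
        hi = frozenset(herb_ingredient)
        it = frozenset(ingredient_target)
        herbs = frozenset(h for h, _ in hi)
        ingredients = frozenset(i for _, i in hi) | frozenset(i for i, _ in it)
        return cls(herbs, ingredients, hi, it)

    # -- lookups ----------------------------------------------------------

    def ingredients_of(self, herb: str) -> list[str]:
        if herb not in self.herbs:
            raise KeyError(f"unknown herb {herb!r}")
        return sorted(i for h, i in self.herb_ingredient if h == herb)

    def targets_of(self, ingredient: str) -> list[str]:
        if ingredient not in self.ingredients:
            raise KeyError(f"unknown ingredient {ingredient!r}")
        return sorted(t for i, t in self.ingredient_target if i == ingredient)

    def herb_targets(self, herb: str) -> list[str]:
        """All distinct proteins targeted by any ingredient of the herb."""
        out: set[str] = set()
        for ing in self.ingredients_of(herb):
            out.update(self.targets_of(ing))
        return sorted(out)

    def targeted_ingredients_of(self, herb: str) -> list[str]:
        """The herb's ingredients that have at least one protein target."""
        return [i for i in self.ingredients_of(herb) if self.targets_of(i)]


def load_catalog(
    herb_ingredient_path: str | Path,
    ingredient_target_path: str | Path,
) -> HerbCatalog:
    """Read the two 2-column TSV association tables."""
    from .network import _read_edge_tsv

    return HerbCatalog.from_pairs(
        _read_edge_tsv(herb_ingredient_path),
        _read_edge_tsv(ingredient_target_path),
    )


def write_catalog(
    catalog: HerbCatalog,
    herb_ingredient_path: str | Path,
    ingredient_target_path: str | Path,
) -> None:
    with Path(herb_ingredient_path).open("w") as fh:
        for h, i in sorted(catalog.herb_ingredient):
            fh.write(f"{h}\t{i}\n")
    with Path(ingredient_target_path).open("w") as fh:
        for i, t in sorted(catalog.ingredient_target):
            fh.write(f"{i}\t{t}\n")


def filter_herbs(catalog: HerbCatalog, min_targeted_ingredients: int = 3) -> HerbCatalog:
    """Drop herbs with fewer than ``min_targeted_ingredients`` ingredients
    that each have at least one protein target.

    Herbs with few active components give too little interaction data for a
    reliable network analysis. Removed herbs are logged. Idempotent.
    """
    kept = frozenset(
        h
        for h in catalog.herbs
        if len(catalog.targeted_ingredients_of(h)) >= min_targeted_ingredients
    )
    removed = sorted(catalog.herbs - kept)
    if removed:
        logger.info(
            "filter_herbs removed %d herbs with <%d targeted ingredients: %s",
            len(removed),
            min_targeted_ingredients,
            ", ".join(removed),
        )
    hi = frozenset((h, i) for h, i in catalog.herb_ingredient if h in kept)
    ingredients = frozenset(i for _, i in hi)
    it = frozenset((i, t) for i, t in catalog.ingredient_target if i in ingredients)
    return HerbCatalog(kept, ingredients, hi, it)


def herb_pathway_counts(catalog: HerbCatalog, herb: str) -> list[TargetCount]:
    """Simple pathway count per protein: how many distinct ingredients of
    ``herb`` target it. Sorted by protein id."""
    counts: dict[str, int] = {}
    for ing in catalog.ingredients_of(herb):
        for t in catalog.targets_of(ing):
            counts[t] = counts.get(t, 0) + 1
    return [TargetCount(p, c) for p, c in sorted(counts.items())]


def top_targets(counts: Sequence[TargetCount], n: int = 50) -> list[str]:
    """The ``n`` proteins with the highest pathway counts.

    Sorted by count descending, ties broken by protein id ascending; returns
    all targets when fewer than ``n`` exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(counts, key=lambda tc: (-tc.pathway_count, tc.protein))
    return [tc.protein for tc in ordered[:n]]
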