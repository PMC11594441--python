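"""Over-representation analysis of a target set against gene-set libraries.

For each term in a library, a one-sided exact test asks whether the target
list contains more of the term's genes than expected from the background;
p-values are Benjamini–Hochberg adjusted across terms. A z-score locates the
observed overlap relative to a random-set null (repeated draws of equally
many genes from the background), and the combined score -ln(p) * z blends
significance and effect size, with larger values indicating stronger
enrichment. Disease-specific terms can be screened out by name pattern.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .prioritize import bh_adjust, hypergeometric_overlap

logger = logging.getLogger("herbwalk.enrich")

DEFAULT_NULL_DRAWS = 1000
DEFAULT_NULL_SEED = 0


@dataclass(frozen=True)
class GeneSetLibrary:
    """Named gene sets (term -> genes) with a source label."""

    gene_sets: Mapping[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for term, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    @property
    def terms(self) -> list[str]:
        return sorted(self.gene_sets)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.gene_sets.values():
            out.update(genes)
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    overlap_k: int
    set_size_m: int
    p_value: float
    adjusted_p: float
    odds_ratio: float
    z_score: float
    combined_score: float
    genes: tuple[str, ...]

    @property
    def overlap(self) -> str:
        return f"{self.overlap_k}/{self.set_size_m}"


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetLibrary:
    """Read a GMT file: term, description, then one gene per column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need term, description, genes")
            term = parts[0].strip()
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            if genes:
                sets[term] = genes
    return GeneSetLibrary(sets, source=source or path.stem)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in library.terms:
            genes = "\t".join(sorted(library.gene_sets[term]))
            fh.write(f"{term}\t{library.source}\t{genes}\n")


def _odds_ratio(k: int, t: int, m: int, n: int) -> float:
    """Odds ratio of the 2x2 table (targets vs rest, in-set vs out)."""
    a, b, c, d = k, t - k, m - k, n - t - m + k
    if b == 0 or c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def over_representation(
    targets: Iterable[str],
    library: GeneSetLibrary,
    background: Iterable[str],
    *,
    n_null_draws: int = DEFAULT_NULL_DRAWS,
    null_seed: int = DEFAULT_NULL_SEED,
) -> list[EnrichmentRecord]:
    """Exact-test enrichment of ``targets`` against every library term.

    Library sets are intersected with the background before testing. The
    z-score null is ``n_null_draws`` seeded uniform draws of ``|targets|``
    genes from the background; the combined score is -ln(p) * z. Records are
    sorted by combined score descending (ties by term).
    """
    background_sorted = sorted(set(background))
    targets_set = set(targets)
    if not background_sorted:
        raise ValueError("background is empty")
    if not targets_set:
        raise ValueError("target set is empty")
    stray = targets_set - set(background_sorted)
    if stray:
        raise ValueError(f"targets outside background: {sorted(stray)[:5]}")

    n_bg = len(background_sorted)
    t = len(targets_set)
    bg_index = {g: i for i, g in enumerate(background_sorted)}

    terms: list[str] = []
    ks: list[int] = []
    ms: list[int] = []
    overlaps: list[tuple[str, ...]] = []
    membership_rows: list[np.ndarray] = []
    for term in library.terms:
        genes = library.gene_sets[term] & set(background_sorted)
        if not genes:
            continue
        hit = sorted(genes & targets_set)
        terms.append(term)
        ks.append(len(hit))
        ms.append(len(genes))
        overlaps.append(tuple(hit))
        row = np.zeros(n_bg, dtype=bool)
        row[[bg_index[g] for g in genes]] = True
        membership_rows.append(row)
    if not terms:
        raise ValueError("no library term intersects the background")

    membership = np.stack(membership_rows)  # terms x background
    rng = np.random.default_rng(null_seed)
    null_counts = np.empty((len(terms), n_null_draws))
    for d in range(n_null_draws):
        draw = rng.choice(n_bg, size=t, replace=False)
        null_counts[:, d] = membership[:, draw].sum(axis=1)
    null_mean = null_counts.mean(axis=1)
    null_sd = null_counts.std(axis=1, ddof=1)

    p_values = [hypergeometric_overlap(k, t, m, n_bg) for k, m in zip(ks, ms)]
    adjusted = bh_adjust(p_values)

    records: list[EnrichmentRecord] = []
    for i, term in enumerate(terms):
        z = 0.0 if null_sd[i] == 0 else float((ks[i] - null_mean[i]) / null_sd[i])
        combined = float(-np.log(p_values[i]) * z)
        records.append(
            EnrichmentRecord(
                term=term,
                overlap_k=ks[i],
                set_size_m=ms[i],
                p_value=p_values[i],
                adjusted_p=adjusted[i],
                odds_ratio=_odds_ratio(ks[i], t, ms[i], n_bg),
                z_score=z,
                combined_score=combined,
                genes=overlaps[i],
            )
        )
    records.sort(key=lambda r: (-r.combined_score, r.term))
    return records


def filter_disease_terms(
    records: Sequence[EnrichmentRecord],
    exclusion_patterns: Sequence[str],
) -> list[EnrichmentRecord]:
    """Drop records whose term matches any exclusion pattern (regex,
    case-insensitive). Removals are logged; an empty pattern list is a
    no-op."""
    if not exclusion_patterns:
        return list(records)
    compiled = [re.compile(p, re.IGNORECASE) for p in exclusion_patterns]
    kept: list[EnrichmentRecord] = []
    removed: list[str] = []
    for rec in records:
        if any(c.search(rec.term) for c in compiled):
            removed.append(rec.term)
        else:
            kept.append(rec)
    if removed:
        logger.info("excluded %d disease-specific terms: %s", len(removed), ", ".join(removed))
    return kept
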