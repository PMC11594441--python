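"""End-to-end orchestration: filter → seed → diffuse → score → rank.

A single declarative :class:`PipelineConfig` (loadable from YAML) carries
every input path and threshold; each output row records a hash of the
resolved configuration so results are traceable to the exact settings that
produced them. All stages are deterministic: identical config and inputs
yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .catalog import (
    HerbCatalog,
    filter_herbs,
    herb_pathway_counts,
    load_catalog,
    top_targets,
)
from .diffusion import (
    DiffusionProfile,
    SeedSet,
    TransitionOperator,
    WalkParameters,
    compute_diffusion_profile,
)
from .mechanism import (
    MechanismSubnetwork,
    SubnetworkParameters,
    build_subnetwork,
    export_subnetwork,
)
from .network import MultiscaleNetwork, load_network
from .prioritize import (
    DiseaseContext,
    RankingRecord,
    core_targets,
    rank_entities,
    significant_ingredient_count,
)

logger = logging.getLogger("herbwalk.pipeline")


@dataclass(frozen=True)
class Thresholds:
    """Prioritization cutoffs, defaulted to the published analysis values."""

    p_cutoff: float = 0.05
    min_significant_ingredients: int = 5
    min_enrichment: float = 5.0
    min_herbs_for_core: int = 3
    min_targeted_ingredients: int = 3
    top_n_targets: int = 50
    top_n_herbs: int = 10
    subnetwork_k: int = 20

    def __post_init__(self) -> None:
        if min(
            self.p_cutoff,
            self.min_significant_ingredients,
            self.min_enrichment,
            self.min_herbs_for_core,
            self.min_targeted_ingredients,
            self.top_n_targets,
            self.top_n_herbs,
            self.subnetwork_k,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    ppi_path: str
    annotation_path: str
    hierarchy_path: str
    herb_ingredient_path: str
    ingredient_target_path: str
    disease_proteins_path: str
    disease_id: str = "disease"
    out_dir: str = "herbwalk_out"
    walk: WalkParameters = field(default_factory=WalkParameters)
    thresholds: Thresholds = field(default_factory=Thresholds)
    correlation_method: str = "pearson"
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        walk = WalkParameters(**raw.pop("walk", {}))
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        return cls(walk=walk, thresholds=thresholds, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (the output directory is
        excluded: it does not affect any computed value)."""
        relevant = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        canonical = json.dumps(relevant, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def write_snapshot(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config": self.to_dict(), "hash": self.config_hash()},
                indent=2,
                sort_keys=True,
            )
        )


def load_disease_proteins(path: str | Path) -> frozenset[str]:
    """One protein id per line; blanks and ``#`` comments skipped."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split("\t")[0])
    return frozenset(out)


def _load_inputs(
    config: PipelineConfig,
) -> tuple[MultiscaleNetwork, HerbCatalog, DiseaseContext]:
    net = load_network(config.ppi_path, config.annotation_path, config.hierarchy_path)
    catalog = load_catalog(config.herb_ingredient_path, config.ingredient_target_path)
    proteins = load_disease_proteins(config.disease_proteins_path)
    mapped = proteins & net.proteins
    if not mapped:
        raise ValueError("no disease protein maps onto the network")
    if len(mapped) < len(proteins):
        logger.info(
            "%d disease proteins not in network, dropped", len(proteins) - len(mapped)
        )
    disease = DiseaseContext(
        disease_id=config.disease_id,
        disease_proteins=mapped,
        population_size=len(net.proteins),
    )
    return net, catalog, disease


def disease_diffusion_profile(
    net: MultiscaleNetwork | TransitionOperator,
    disease: DiseaseContext,
    walk: WalkParameters,
) -> DiffusionProfile:
    return compute_diffusion_profile(
        net, SeedSet.uniform(disease.disease_proteins), walk
    )


def score_herbs(
    net: MultiscaleNetwork,
    catalog: HerbCatalog,
    disease: DiseaseContext,
    walk: WalkParameters = WalkParameters(),
    thresholds: Thresholds = Thresholds(),
    correlation_method: str = "pearson",
) -> tuple[list[RankingRecord], HerbCatalog]:
    """Filter the catalog, diffuse every herb and the disease, rank herbs.

    Returns the ranking records and the filtered catalog (whose herbs the
    records cover). Each herb is seeded with its top targets by pathway
    count, uniformly weighted.
    """
    retained = filter_herbs(catalog, thresholds.min_targeted_ingredients)
    operator = TransitionOperator(net, walk)
    disease_profile = disease_diffusion_profile(operator, disease, walk)

    profiles: dict[str, DiffusionProfile] = {}
    herb_top: dict[str, list[str]] = {}
    sig_counts: dict[str, int] = {}
    for herb in sorted(retained.herbs):
        counts = herb_pathway_counts(retained, herb)
        top = top_targets(counts, thresholds.top_n_targets)
        seeds = SeedSet.uniform(top).restrict_to(net.proteins)
        profiles[herb] = compute_diffusion_profile(operator, seeds, walk)
        herb_top[herb] = [t for t in top if t in net.proteins]
        sig_counts[herb] = significant_ingredient_count(
            retained, herb, disease, thresholds.p_cutoff
        )

    records = rank_entities(
        profiles,
        herb_top,
        disease,
        disease_profile,
        method=correlation_method,
        p_cutoff=thresholds.p_cutoff,
        min_enrichment=thresholds.min_enrichment,
        min_significant_ingredients=thresholds.min_significant_ingredients,
        significant_ingredients=sig_counts,
    )
    return records, retained


def score_ingredients(
    net: MultiscaleNetwork,
    catalog: HerbCatalog,
    herb: str,
    disease: DiseaseContext,
    walk: WalkParameters = WalkParameters(),
    thresholds: Thresholds = Thresholds(),
    correlation_method: str = "pearson",
) -> list[RankingRecord]:
    """Rank one herb's ingredients: each seeded with its full target set."""
    operator = TransitionOperator(net, walk)
    disease_profile = disease_diffusion_profile(operator, disease, walk)
    profiles: dict[str, DiffusionProfile] = {}
    ing_targets: dict[str, list[str]] = {}
    for ing in catalog.targeted_ingredients_of(herb):
        targets = catalog.targets_of(ing)
        seeds = SeedSet.uniform(targets).restrict_to(net.proteins)
        profiles[ing] = compute_diffusion_profile(operator, seeds, walk)
        ing_targets[ing] = [t for t in targets if t in net.proteins]
    if not profiles:
        raise ValueError(f"herb {herb!r} has no targeted ingredients")
    return rank_entities(
        profiles,
        ing_targets,
        disease,
        disease_profile,
        method=correlation_method,
        p_cutoff=thresholds.p_cutoff,
        min_enrichment=thresholds.min_enrichment,
    )


def _records_frame(records: Sequence[RankingRecord], config_hash: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity": [r.entity for r in records],
            "correlation_score": [r.correlation_score for r in records],
            "overlap": [r.overlap for r in records],
            "p_value": [r.hypergeom_p for r in records],
            "adjusted_p": [r.adjusted_p for r in records],
            "enrichment": [r.enrichment for r in records],
            "n_significant_ingredients": [
                r.n_significant_ingredients for r in records
            ],
            "prioritized": [r.prioritized for r in records],
            "config_hash": config_hash,
        }
    )


def run_rank_herbs(config: PipelineConfig) -> dict[str, Path]:
    """Full herb-ranking stage; writes ranking CSV, core-target CSV, and a
    resolved-config snapshot into ``config.out_dir``."""
    net, catalog, disease = _load_inputs(config)
    records, retained = score_herbs(
        net,
        catalog,
        disease,
        config.walk,
        config.thresholds,
        config.correlation_method,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    ranking_path = out / "herb_ranking.csv"
    _records_frame(records, chash).to_csv(ranking_path, index=False)

    top = [r.entity for r in records[: config.thresholds.top_n_herbs]]
    core = core_targets(retained, top, config.thresholds.min_herbs_for_core)
    core_path = out / "core_targets.csv"
    pd.DataFrame(
        {
            "protein": core.proteins(),
            "n_top_herbs": [core.counts[p] for p in core.proteins()],
            "config_hash": chash,
        }
    ).to_csv(core_path, index=False)

    snap = out / "config_snapshot.json"
    config.write_snapshot(snap)
    return {"ranking": ranking_path, "core_targets": core_path, "config": snap}


def run_rank_ingredients(config: PipelineConfig, herb: str) -> Path:
    """Ingredient ranking CSV for one herb retained by the filter."""
    net, catalog, disease = _load_inputs(config)
    retained = filter_herbs(catalog, config.thresholds.min_targeted_ingredients)
    if herb not in retained.herbs:
        raise KeyError(f"herb {herb!r} absent after filtering")
    records = score_ingredients(
        net,
        retained,
        herb,
        disease,
        config.walk,
        config.thresholds,
        config.correlation_method,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"ingredients_{herb}.csv"
    frame = _records_frame(records, config.config_hash())
    frame = frame.drop(columns=["n_significant_ingredients"])
    frame.to_csv(path, index=False)
    return path


def run_subnetwork(config: PipelineConfig, ingredient: str) -> dict[str, Path]:
    """Mechanism subnetwork (SIF + GraphML + node annotations) for one
    ingredient against the configured disease."""
    net, catalog, disease = _load_inputs(config)
    targets = catalog.targets_of(ingredient)
    seeds = SeedSet.uniform(targets).restrict_to(net.proteins)
    operator = TransitionOperator(net, config.walk)
    profile_ing = compute_diffusion_profile(operator, seeds, config.walk)
    profile_dis = disease_diffusion_profile(operator, disease, config.walk)
    sub = build_subnetwork(
        net,
        seeds,
        disease,
        profile_ing,
        profile_dis,
        SubnetworkParameters(k=config.thresholds.subnetwork_k),
        ingredient_id=ingredient,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    safe = ingredient.replace(":", "_").replace("/", "_")
    paths = {
        "sif": export_subnetwork(sub, out / f"subnetwork_{safe}.sif", "sif"),
        "graphml": export_subnetwork(
            sub, out / f"subnetwork_{safe}.graphml", "graphml"
        ),
    }
    annot = out / f"subnetwork_{safe}_nodes.csv"
    pd.DataFrame(sub.node_table()).to_csv(annot, index=False)
    paths["nodes"] = annot
    return paths
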