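"""End-to-end orchestration: filter -> map -> overlap -> terms -> stats.

The pipeline mirrors the analysis funnel: catalog records are filtered by
study count and SNP significance, SNPs are mapped to genes (overlap or LD),
per-category gene sets are intersected and clustered, GO term sets are
compiled per category and intersected, the all-category term overlap is
tested for internal Wang similarity against the background term universe,
genes shared by at least three categories are tested for GO enrichment
against the full gene universe, and Fisher's combined probability of the
per-study significance threshold is reported for the overlap depths.

``analyze`` is the in-memory core; ``run_pipeline`` wraps it with file I/O
and persists every stage table so downstream stages can be re-run from disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    FilterPolicy,
    GwasRecord,
    TraitCategoryMap,
    assign_categories,
    filter_traits,
    read_catalog,
    write_records,
)
from .mapping import (
    GeneIndex,
    LdIndex,
    SnpLocation,
    build_category_gene_sets,
    read_bed,
    read_ld_pairs,
    read_snp_locations,
)
from .ontology import GoDag, AnnotationMap, compile_term_sets, read_annotations, read_obo
from .semsim import EdgeWeights, WangSimilarity, overlap_vs_background_test
from .setops import cluster_categories, overlap, pairwise_similarity
from .stats import fisher_combined, hypergeom_enrichment

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "analyze",
    "analyze_bundle",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Paths to the seven inputs plus every analysis knob."""

    catalog: str
    snp_locations: str
    genes: str
    ld_pairs: str
    obo: str
    annotations: str
    category_map: str
    min_studies: int = 5
    p_max: float = 1e-5
    strict_less: bool = True
    r2_min: float = 0.8
    similarity_mode: str = "shared_over_universe"
    linkage: str = "average"
    namespace: str | None = "biological_process"
    propagate: bool = False
    w_is_a: float = 0.8
    w_part_of: float = 0.6
    background_mode: str = "all"  # "all" | "exclusive"
    overlap_m: int | None = None  # term-overlap depth for the semsim test
    enrich_m: int = 3  # gene-overlap depth for GO enrichment
    exact_limit: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("catalog", "snp_locations", "genes", "ld_pairs", "obo",
                     "annotations", "category_map"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} input missing: {p}")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Objects + JSON-ready report for one pipeline run."""

    filtered_records: list[GwasRecord]
    trait_summary: pd.DataFrame
    gene_sets: Mapping[str, set[str]]
    gene_universe: set[str]
    gene_overlap: object
    gene_similarity: object
    gene_newick: str
    term_sets: Mapping[str, set[str]]
    term_universe: set[str]
    term_overlap: object
    term_similarity: object
    term_newick: str
    shared_genes: set[str]  # at_least(enrich_m)
    enrichment: list
    semsim_result: object | None
    fisher: dict
    report: dict


def analyze(
    records: list[GwasRecord],
    category_map: TraitCategoryMap,
    locations: Mapping[str, SnpLocation],
    gene_index: GeneIndex,
    ld_index: LdIndex,
    dag: GoDag,
    annotations: AnnotationMap,
    config: PipelineConfig,
) -> PipelineResult:
    policy = FilterPolicy(
        min_studies=config.min_studies,
        p_max=config.p_max,
        strict_less=config.strict_less,
    )
    filtered, trait_summary = filter_traits(records, policy)
    cat_traits, tagged, side = assign_categories(filtered, category_map)
    gene_sets, map_report = build_category_gene_sets(
        tagged, locations, gene_index, ld_index, r2_min=config.r2_min
    )

    gene_overlap = overlap(gene_sets.sets)
    gene_sim = pairwise_similarity(gene_sets.sets, mode=config.similarity_mode)
    _, gene_leaves, gene_newick = cluster_categories(gene_sim, method=config.linkage)

    term_sets, unannotated = compile_term_sets(
        gene_sets, annotations, dag=dag,
        propagate=config.propagate, exclude_roots=True,
    )
    term_overlap = overlap(term_sets.sets)
    term_sim = pairwise_similarity(term_sets.sets, mode=config.similarity_mode)
    _, term_leaves, term_newick = cluster_categories(term_sim, method=config.linkage)

    n_cats = len(gene_sets.sets)
    overlap_m = config.overlap_m if config.overlap_m is not None else n_cats
    overlap_terms = term_overlap.at_least(overlap_m)
    if config.background_mode == "exclusive":
        background_terms = term_sets.universe - overlap_terms
    else:
        background_terms = set(term_sets.universe)
    semsim_result = None
    if len(overlap_terms) >= 2 and len(background_terms) >= 2:
        engine = WangSimilarity(
            dag, EdgeWeights(w_is_a=config.w_is_a, w_part_of=config.w_part_of)
        )
        semsim_result = overlap_vs_background_test(
            overlap_terms, background_terms, dag,
            exact_limit=config.exact_limit, engine=engine,
        )

    shared_genes = gene_overlap.at_least(config.enrich_m)
    enrichment = []
    if shared_genes and gene_sets.universe:
        enrichment = hypergeom_enrichment(
            shared_genes, set(gene_sets.universe), annotations
        )

    fisher = {
        f"combined_p_{m}_tests": fisher_combined([config.p_max] * m).p_combined
        for m in (config.enrich_m, n_cats)
    }

    report = {
        "version": __version__,
        "config_digest": config.digest(),
        "n_input_records": len(records),
        "n_filtered_records": len(filtered),
        "n_traits": int(len(trait_summary)),
        "categories": sorted(gene_sets.sets),
        "side_channel": {k: sorted(v) for k, v in side.items()},
        "mapping": map_report,
        "n_genes_universe": len(gene_sets.universe),
        "gene_overlap_all": sorted(gene_overlap.at_least(n_cats)),
        "gene_overlap_all_fraction": gene_overlap.shared_fraction(),
        "shared_genes_at_least_m": sorted(shared_genes),
        "enrich_m": config.enrich_m,
        "n_terms_universe": len(term_sets.universe),
        "term_overlap_all": len(term_overlap.at_least(n_cats)),
        "term_overlap_all_fraction": term_overlap.shared_fraction(),
        "term_overlap_m": overlap_m,
        "n_overlap_terms_tested": len(overlap_terms),
        "unannotated_genes": unannotated,
        "gene_leaf_order": gene_leaves,
        "term_leaf_order": term_leaves,
        "semsim": semsim_result.to_dict() if semsim_result else None,
        "fisher": fisher,
        "n_enriched_terms_q05": sum(1 for r in enrichment if r.q_value < 0.05),
    }
    return PipelineResult(
        filtered_records=filtered,
        trait_summary=trait_summary,
        gene_sets=gene_sets.sets,
        gene_universe=set(gene_sets.universe),
        gene_overlap=gene_overlap,
        gene_similarity=gene_sim,
        gene_newick=gene_newick,
        term_sets=term_sets.sets,
        term_universe=set(term_sets.universe),
        term_overlap=term_overlap,
        term_similarity=term_sim,
        term_newick=term_newick,
        shared_genes=shared_genes,
        enrichment=enrichment,
        semsim_result=semsim_result,
        fisher=fisher,
        report=report,
    )


def analyze_bundle(bundle, **overrides) -> PipelineResult:
    """Run the full analysis on an in-memory synthetic bundle (no file I/O).

    Keyword overrides set any :class:`PipelineConfig` analysis knob; the
    path fields are unused on this route.
    """
    placeholder = {name: "<in-memory>" for name in (
        "catalog", "snp_locations", "genes", "ld_pairs", "obo",
        "annotations", "category_map")}
    config = PipelineConfig(**placeholder, **overrides)
    return analyze(
        bundle.records(),
        bundle.category_map,
        bundle.snp_locations,
        GeneIndex(bundle.gene_intervals),
        LdIndex(bundle.ld_pairs),
        bundle.dag,
        bundle.annotation_map(),
        config,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Load the seven inputs, run :func:`analyze`, persist every stage table."""
    config.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, parse_report = read_catalog(config.catalog)
    category_map = TraitCategoryMap.from_tsv(config.category_map)
    locations = read_snp_locations(config.snp_locations)
    gene_index = GeneIndex(read_bed(config.genes))
    ld_index = LdIndex(read_ld_pairs(config.ld_pairs))
    dag = read_obo(config.obo)
    annotations = read_annotations(
        config.annotations, dag, namespace_filter=config.namespace
    )

    result = analyze(
        records, category_map, locations, gene_index, ld_index, dag,
        annotations, config,
    )
    result.report["parse"] = parse_report.to_dict()

    write_records(result.filtered_records, out / "filtered_records.tsv")
    result.trait_summary.to_csv(out / "trait_summary.tsv", sep="\t", index=False)
    _write_sets(result.gene_sets, out / "category_genes.tsv")
    result.gene_overlap.to_frame().to_csv(out / "gene_overlap.tsv", sep="\t", index=False)
    result.gene_similarity.to_frame().to_csv(out / "gene_similarity.tsv", sep="\t")
    (out / "gene_dendrogram.nwk").write_text(result.gene_newick + "\n", encoding="utf-8")
    _write_sets(result.term_sets, out / "category_terms.tsv")
    result.term_overlap.to_frame().to_csv(out / "term_overlap.tsv", sep="\t", index=False)
    result.term_similarity.to_frame().to_csv(out / "term_similarity.tsv", sep="\t")
    (out / "term_dendrogram.nwk").write_text(result.term_newick + "\n", encoding="utf-8")
    if result.enrichment:
        pd.DataFrame([dataclasses.asdict(r) for r in result.enrichment]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
    report = dict(result.report)
    report["generated_at"] = datetime.now(timezone.utc).isoformat()
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    return result


def _write_sets(sets: Mapping[str, set[str]], path: Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("category\titem\n")
        for cat in sorted(sets):
            for item in sorted(sets[cat]):
                fh.write(f"{cat}\t{item}\n")
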