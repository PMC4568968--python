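"""Synthetic GWAS-catalog / LD / ontology bundles with a planted pathway.

The generator emulates the statistical structure the analysis assumes: five
disease categories whose gene sets are mostly category-exclusive, a planted
core of genes shared by exactly ``m_shared`` categories, a toy GO DAG (a
rooted tree plus extra ``part_of`` edges so diamond paths exist), a planted
"aging pathway" — a connected subtree of terms annotated to every shared
gene — and uniform annotation noise on all genes.  Catalog SNPs reach their
genes either by direct overlap or through a high-r2 LD bridge; low-r2 decoy
pairs are present so the threshold matters.

Everything is reproducible per seed, both as in-memory objects and as the
seven on-disk files the pipeline readers consume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import GwasRecord, TraitCategoryMap, ANALYSIS_CATEGORIES
from .mapping import GeneInterval, LdPair, SnpLocation
from .ontology import AnnotationMap, GoDag

__all__ = ["SimulationParams", "Bundle", "generate", "null_bundle", "write_bundle"]

GENE_LENGTH = 2_000
GENE_SPACING = 10_000
BRIDGE_OFFSET = 3_000  # intergenic catalog SNP sits this far left of its gene


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults define the standard conditions."""

    seed: int = 0
    n_categories: int = 5
    genes_per_category: int = 30  # category-exclusive genes
    n_shared_genes: int = 10  # planted into exactly m_shared categories each
    m_shared: int = 3
    dag_depth: int = 5
    dag_branching: int = 3
    part_of_fraction: float = 0.1  # extra part_of edges (diamonds)
    planted_module_size: int = 10  # connected GO subtree annotating shared genes
    annotation_noise: int = 2  # uniform random terms per gene
    snps_per_gene: int = 2
    p_sig_range: tuple[float, float] = (1e-12, 1e-6)  # log-uniform, significant
    p_distractor_range: tuple[float, float] = (1e-4, 0.5)  # fails the filter
    n_distractors_per_trait: int = 3
    fraction_ld_mapped: float = 0.3
    r2_bridge_range: tuple[float, float] = (0.8, 1.0)
    r2_decoy_range: tuple[float, float] = (0.1, 0.6)
    n_studies_per_trait: int = 5

    def __post_init__(self) -> None:
        if self.m_shared > self.n_categories:
            raise ValueError("m_shared cannot exceed n_categories")
        if self.n_shared_genes and self.genes_per_category < 1:
            raise ValueError("need at least one exclusive gene per category")
        if not (0.0 <= self.fraction_ld_mapped <= 1.0):
            raise ValueError("fraction_ld_mapped must lie in [0, 1]")
        for name in ("n_categories", "genes_per_category", "dag_depth",
                     "dag_branching", "snps_per_gene", "n_studies_per_trait"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class Bundle:
    """In-memory synthetic inputs plus the ground-truth manifest."""

    params: SimulationParams
    catalog_rows: list[dict]  # NHGRI-dialect rows
    snp_locations: dict[str, SnpLocation]
    gene_intervals: list[GeneInterval]
    ld_pairs: list[LdPair]
    dag: GoDag
    annotations: dict[str, set[str]]  # gene -> direct GO terms
    category_map: TraitCategoryMap
    manifest: dict

    def annotation_map(self) -> AnnotationMap:
        return AnnotationMap(by_gene={g: set(t) for g, t in self.annotations.items()})

    def records(self) -> list[GwasRecord]:
        """Catalog rows expanded to one record per rsid (reader semantics)."""
        out: list[GwasRecord] = []
        for row in self.catalog_rows:
            for rsid in row["SNPS"].replace(",", ";").split(";"):
                rsid = rsid.strip()
                if rsid:
                    out.append(
                        GwasRecord(
                            trait=row["DISEASE/TRAIT"],
                            study_id=row["PUBMEDID"],
                            rsid=rsid,
                            p_value=float(row["P-VALUE"]),
                        )
                    )
        return out


def _make_dag(params: SimulationParams, rng: np.random.Generator) -> tuple[GoDag, list[str]]:
    """Complete b-ary tree of the requested depth, plus part_of cross edges.

    Returns the DAG and the planted module: a connected subtree rooted at a
    random depth-2 node, truncated to ``planted_module_size`` terms in BFS
    order (empty when the module size is zero).
    """
    b, depth = params.dag_branching, params.dag_depth
    ids: list[str] = []
    level_of: dict[str, int] = {}
    children: dict[str, list[str]] = {}
    counter = 1

    def new_id() -> str:
        nonlocal counter
        tid = f"GO:{counter:07d}"
        counter += 1
        return tid

    root = new_id()
    ids.append(root)
    level_of[root] = 0
    parents: dict[str, list[tuple[str, str]]] = {}
    frontier = [root]
    for d in range(1, depth + 1):
        nxt = []
        for parent in frontier:
            for _ in range(b):
                tid = new_id()
                ids.append(tid)
                level_of[tid] = d
                parents[tid] = [(parent, "is_a")]
                children.setdefault(parent, []).append(tid)
                nxt.append(tid)
        frontier = nxt

    # extra part_of edges toward strictly shallower non-ancestor nodes
    non_root = ids[1:]
    n_extra = int(round(params.part_of_fraction * len(non_root)))
    picks = rng.choice(len(non_root), size=n_extra, replace=False) if n_extra else []
    for idx in sorted(int(i) for i in picks):
        child = non_root[idx]
        shallower = [t for t in ids if level_of[t] < level_of[child]
                     and t != parents[child][0][0]]
        if shallower:
            target = shallower[int(rng.integers(len(shallower)))]
            parents[child] = sorted(parents[child] + [(target, "part_of")])

    terms = {t: {"name": f"synthetic process {t[3:]}", "namespace": "biological_process",
                 "obsolete": False} for t in ids}
    dag = GoDag(terms=terms, parents={t: tuple(p) for t, p in parents.items()})

    module: list[str] = []
    if params.planted_module_size > 0:
        depth2 = [t for t in ids if level_of[t] == min(2, depth)]
        anchor = depth2[int(rng.integers(len(depth2)))]
        queue = [anchor]
        while queue and len(module) < params.planted_module_size:
            t = queue.pop(0)
            module.append(t)
            queue.extend(children.get(t, []))
    return dag, module


def generate(params: SimulationParams = SimulationParams()) -> Bundle:
    """Build one complete input bundle plus its ground-truth manifest."""
    rng = np.random.default_rng(params.seed)
    dag, module = _make_dag(params, rng)
    all_terms = [t for t in sorted(dag.terms) if dag.parents.get(t)]  # non-root

    cats = list(ANALYSIS_CATEGORIES[: params.n_categories])
    if params.n_categories > len(ANALYSIS_CATEGORIES):
        raise ValueError("n_categories exceeds the category vocabulary")

    # --- genes ---------------------------------------------------------
    gene_counter = 0

    def new_genes(n: int, prefix: str) -> list[str]:
        nonlocal gene_counter
        out = []
        for _ in range(n):
            out.append(f"{prefix}{gene_counter:04d}")
            gene_counter += 1
        return out

    exclusive = {c: new_genes(params.genes_per_category, "G") for c in cats}
    shared = new_genes(params.n_shared_genes, "SHR")
    side_genes = {
        "longevity": new_genes(5, "LON"),
        "non_age_related": new_genes(5, "NAR"),
        "understudied": new_genes(3, "RAR"),
    }
    all_genes = [g for gs in exclusive.values() for g in gs] + shared + [
        g for gs in side_genes.values() for g in gs
    ]
    intervals = [
        GeneInterval(gene_id=g, chrom="chr1", start=(i + 1) * GENE_SPACING,
                     end=(i + 1) * GENE_SPACING + GENE_LENGTH)
        for i, g in enumerate(all_genes)
    ]
    gene_start = {iv.gene_id: iv.start for iv in intervals}

    shared_assignment: dict[str, list[str]] = {}
    category_genes = {c: set(exclusive[c]) for c in cats}
    for g in shared:
        chosen = sorted(rng.choice(cats, size=params.m_shared, replace=False))
        shared_assignment[g] = list(chosen)
        for c in chosen:
            category_genes[c].add(g)

    # --- catalog, SNP locations, LD ------------------------------------
    snp_counter = 1
    locations: dict[str, SnpLocation] = {}
    ld_pairs: list[LdPair] = []
    catalog_rows: list[dict] = []
    study_counter = 1

    def new_rsid() -> str:
        nonlocal snp_counter
        rsid = f"rs{snp_counter}"
        snp_counter += 1
        return rsid

    def place(rsid: str, pos: int) -> None:
        locations[rsid] = SnpLocation(rsid=rsid, chrom="chr1", pos=pos)

    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def emit_trait(trait: str, genes: list[str], n_studies: int) -> None:
        nonlocal study_counter
        studies = [f"PM{study_counter + i}" for i in range(n_studies)]
        study_counter += n_studies
        row_i = 0
        for g in sorted(genes):
            start = gene_start[g]
            rsids = []
            for s in range(params.snps_per_gene):
                rsid = new_rsid()
                inside = start + 100 + int(rng.integers(GENE_LENGTH - 200))
                if rng.random() < params.fraction_ld_mapped:
                    # catalog SNP intergenic; a high-r2 partner sits on the gene
                    place(rsid, start - BRIDGE_OFFSET - s * 50)
                    partner = new_rsid()
                    place(partner, inside)
                    ld_pairs.append(LdPair(rsid, partner, round(
                        float(rng.uniform(*params.r2_bridge_range)), 3)))
                    # sometimes a low-r2 decoy to a foreign gene
                    if rng.random() < 0.3:
                        other = all_genes[int(rng.integers(len(all_genes)))]
                        decoy = new_rsid()
                        place(decoy, gene_start[other] + 500)
                        ld_pairs.append(LdPair(rsid, decoy, round(
                            float(rng.uniform(*params.r2_decoy_range)), 3)))
                else:
                    place(rsid, inside)
                rsids.append(rsid)
            p = log_uniform(*params.p_sig_range)
            # half the multi-SNP genes report both rsids in one catalog cell
            if len(rsids) > 1 and rng.random() < 0.5:
                catalog_rows.append({
                    "DISEASE/TRAIT": trait,
                    "PUBMEDID": studies[row_i % n_studies],
                    "SNPS": "; ".join(rsids),
                    "P-VALUE": f"{p:.3e}",
                })
                row_i += 1
            else:
                for rsid in rsids:
                    catalog_rows.append({
                        "DISEASE/TRAIT": trait,
                        "PUBMEDID": studies[row_i % n_studies],
                        "SNPS": rsid,
                        "P-VALUE": f"{p:.3e}",
                    })
                    row_i += 1
        for _ in range(params.n_distractors_per_trait):
            rsid = new_rsid()
            g = all_genes[int(rng.integers(len(all_genes)))]
            place(rsid, gene_start[g] + 700)
            catalog_rows.append({
                "DISEASE/TRAIT": trait,
                "PUBMEDID": studies[row_i % n_studies],
                "SNPS": rsid,
                "P-VALUE": f"{log_uniform(*params.p_distractor_range):.3e}",
            })
            row_i += 1

    map_entries: dict[str, str] = {}
    for cat in cats:
        trait = f"{cat} trait"
        map_entries[trait] = cat
        emit_trait(trait, sorted(category_genes[cat]), params.n_studies_per_trait)
    map_entries["Longevity"] = "longevity"
    emit_trait("Longevity", side_genes["longevity"], params.n_studies_per_trait)
    map_entries["Eye color"] = "non_age_related"
    emit_trait("Eye color", side_genes["non_age_related"], params.n_studies_per_trait)
    map_entries["Understudied trait"] = "other"
    emit_trait("Understudied trait", side_genes["understudied"], 2)  # < min_studies

    # --- annotations ----------------------------------------------------
    annotations: dict[str, set[str]] = {}
    for g in all_genes:
        noise = rng.choice(len(all_terms), size=params.annotation_noise, replace=False)
        annotations[g] = {all_terms[int(i)] for i in noise}
    for g in shared:
        annotations[g] |= set(module)

    manifest = {
        "seed": params.seed,
        "planted_shared_genes": sorted(shared),
        "shared_gene_categories": {g: shared_assignment[g] for g in sorted(shared)},
        "planted_module_terms": sorted(module),
        "m_shared": params.m_shared,
        "expected_at_least_m_genes": sorted(shared),
        "category_gene_sets": {c: sorted(category_genes[c]) for c in cats},
    }
    return Bundle(
        params=params,
        catalog_rows=catalog_rows,
        snp_locations=locations,
        gene_intervals=intervals,
        ld_pairs=ld_pairs,
        dag=dag,
        annotations=annotations,
        category_map=TraitCategoryMap(dict(map_entries)),
        manifest=manifest,
    )


def null_bundle(params: SimulationParams = SimulationParams()) -> Bundle:
    """Bundle with no planted structure (no shared genes, no GO module)."""
    return generate(
        dataclasses.replace(params, n_shared_genes=0, planted_module_size=0)
    )


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize the bundle as the seven pipeline input files + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": out / "catalog.tsv",
        "snp_locations": out / "snp_locations.tsv",
        "genes": out / "genes.bed",
        "ld_pairs": out / "ld_pairs.tsv",
        "obo": out / "ontology.obo",
        "annotations": out / "annotations.tsv",
        "category_map": out / "categories.tsv",
        "manifest": out / "manifest.json",
    }
    with paths["catalog"].open("w", encoding="utf-8") as fh:
        fh.write("DISEASE/TRAIT\tPUBMEDID\tSNPS\tP-VALUE\n")
        for row in bundle.catalog_rows:
            fh.write(f"{row['DISEASE/TRAIT']}\t{row['PUBMEDID']}\t"
                     f"{row['SNPS']}\t{row['P-VALUE']}\n")
    with paths["snp_locations"].open("w", encoding="utf-8") as fh:
        fh.write("rsid\tchrom\tpos\n")
        for rsid in sorted(bundle.snp_locations, key=lambda r: int(r[2:])):
            loc = bundle.snp_locations[rsid]
            fh.write(f"{loc.rsid}\t{loc.chrom}\t{loc.pos + 1}\n")  # 1-based on disk
    with paths["genes"].open("w", encoding="utf-8") as fh:
        for iv in bundle.gene_intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_id}\n")
    with paths["ld_pairs"].open("w", encoding="utf-8") as fh:
        fh.write("rsid_a\trsid_b\tr2\n")
        for p in bundle.ld_pairs:
            fh.write(f"{p.rsid_a}\t{p.rsid_b}\t{p.r2}\n")
    with paths["obo"].open("w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(bundle.dag.terms):
            info = bundle.dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {info['name']}\n"
                     f"namespace: {info['namespace']}\n")
            for parent, rel in bundle.dag.parents.get(tid, ()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
    with paths["annotations"].open("w", encoding="utf-8") as fh:
        for gene in sorted(bundle.annotations):
            for term in sorted(bundle.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
    with paths["category_map"].open("w", encoding="utf-8") as fh:
        for trait in sorted(bundle.category_map.entries):
            fh.write(f"{trait}\t{bundle.category_map.entries[trait]}\n")
    paths["manifest"].write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return paths
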