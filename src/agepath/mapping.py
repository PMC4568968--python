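"""SNP-to-gene assignment by genomic overlap or linkage disequilibrium.

A trait-associated SNP is assigned to every gene whose interval contains it,
and additionally to every gene containing an LD partner SNP with r-squared
at or above a threshold (depth 1 only: LD is not chained transitively).
Coordinates are 0-based half-open throughout (BED convention); 1-based SNP
position tables are converted on read.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .catalog import GwasRecord

__all__ = [
    "GeneInterval",
    "SnpLocation",
    "LdPair",
    "CategoryGeneSets",
    "GeneIndex",
    "LdIndex",
    "map_snp_to_genes",
    "build_category_gene_sets",
    "read_bed",
    "read_snp_locations",
    "read_ld_pairs",
]


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int
    end: int
    symbol: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class SnpLocation:
    rsid: str
    chrom: str
    pos: int  # 0-based

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass(frozen=True)
class LdPair:
    """Unordered SNP pair with its r-squared."""

    rsid_a: str
    rsid_b: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must be in [0, 1]")


@dataclass
class CategoryGeneSets:
    """Per-category unique gene sets plus their union (the gene universe)."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        union = set().union(*self.sets.values()) if self.sets else set()
        if not self.universe:
            self.universe = union
        elif self.universe != union:
            raise ValueError("universe does not equal union of category sets")


class GeneIndex:
    """Sorted-interval lookup of genes overlapping a point, per chromosome."""

    def __init__(self, intervals: Iterable[GeneInterval]):
        by_chrom: dict[str, list[GeneInterval]] = {}
        seen: set[str] = set()
        for iv in intervals:
            if iv.gene_id in seen:
                raise ValueError(f"duplicate gene_id {iv.gene_id!r}")
            seen.add(iv.gene_id)
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._ivs: dict[str, list[GeneInterval]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end, iv.gene_id))
            self._ivs[chrom] = ivs
            self._starts[chrom] = [iv.start for iv in ivs]

    def overlapping(self, chrom: str, pos: int) -> set[str]:
        ivs = self._ivs.get(chrom)
        if not ivs:
            return set()
        hi = bisect.bisect_right(self._starts[chrom], pos)
        # genes are short relative to chromosome span; linear scan back is fine
        return {iv.gene_id for iv in ivs[:hi] if iv.end > pos}


class LdIndex:
    """Symmetric rsid -> [(partner rsid, r2)] lookup."""

    def __init__(self, pairs: Iterable[LdPair]):
        self._partners: dict[str, list[tuple[str, float]]] = {}
        for p in pairs:
            self._partners.setdefault(p.rsid_a, []).append((p.rsid_b, p.r2))
            self._partners.setdefault(p.rsid_b, []).append((p.rsid_a, p.r2))

    def partners(self, rsid: str, r2_min: float) -> list[str]:
        return [b for b, r2 in self._partners.get(rsid, []) if r2 >= r2_min]


def map_snp_to_genes(
    rsid: str,
    locations: Mapping[str, SnpLocation],
    genes: GeneIndex,
    ld: LdIndex,
    r2_min: float = 0.8,
) -> set[str]:
    """Genes containing the SNP, plus genes containing any LD partner.

    r2_min must lie in (0, 1]; partners qualify at r2 >= r2_min.  A SNP with
    no known location and no qualifying located partner maps to the empty
    set (the caller counts it as unmapped).
    """
    if not (0.0 < r2_min <= 1.0):
        raise ValueError("r2_min must be in (0, 1]")
    hits: set[str] = set()
    loc = locations.get(rsid)
    if loc is not None:
        hits |= genes.overlapping(loc.chrom, loc.pos)
    for partner in ld.partners(rsid, r2_min):
        ploc = locations.get(partner)
        if ploc is not None:
            hits |= genes.overlapping(ploc.chrom, ploc.pos)
    return hits


def build_category_gene_sets(
    records: Iterable[GwasRecord],
    locations: Mapping[str, SnpLocation],
    genes: GeneIndex,
    ld: LdIndex,
    r2_min: float = 0.8,
) -> tuple[CategoryGeneSets, dict[str, dict[str, int]]]:
    """Union the gene assignments of every category's SNPs.

    Records must carry category tags.  Returns the per-category gene sets
    and a mapping report ``category -> {n_snps, n_mapped, n_unmapped}``
    counted over distinct rsids.
    """
    by_cat_snps: dict[str, set[str]] = {}
    for rec in records:
        if rec.category is None:
            raise ValueError(f"record for {rec.rsid} lacks a category tag")
        by_cat_snps.setdefault(rec.category, set()).add(rec.rsid)

    sets: dict[str, set[str]] = {}
    report: dict[str, dict[str, int]] = {}
    cache: dict[str, set[str]] = {}
    for cat in sorted(by_cat_snps):
        cat_genes: set[str] = set()
        n_unmapped = 0
        for rsid in by_cat_snps[cat]:
            if rsid not in cache:
                cache[rsid] = map_snp_to_genes(rsid, locations, genes, ld, r2_min)
            hit = cache[rsid]
            if hit:
                cat_genes |= hit
            else:
                n_unmapped += 1
        sets[cat] = cat_genes
        report[cat] = {
            "n_snps": len(by_cat_snps[cat]),
            "n_mapped": len(by_cat_snps[cat]) - n_unmapped,
            "n_unmapped": n_unmapped,
        }
    return CategoryGeneSets(sets=sets), report


# ---------------------------------------------------------------------------
# readers


def read_bed(path: str | Path) -> list[GeneInterval]:
    """BED4: chrom, start, end, gene_id (0-based half-open)."""
    out: list[GeneInterval] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(GeneInterval(gene_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2])))
    return out


def read_snp_locations(
    path: str | Path, one_based: bool = True
) -> dict[str, SnpLocation]:
    """TSV rsid/chrom/pos with a header; positions converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str, "pos": int})
    offset = 1 if one_based else 0
    return {
        r.rsid: SnpLocation(rsid=r.rsid, chrom=r.chrom, pos=int(r.pos) - offset)
        for r in df.itertuples()
    }


def read_ld_pairs(path: str | Path) -> list[LdPair]:
    """TSV rsid_a/rsid_b/r2 with a header."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str, "r2": float})
    return [LdPair(r.rsid_a, r.rsid_b, float(r.r2)) for r in df.itertuples()]
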