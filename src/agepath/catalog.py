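"""Reading and filtering of GWAS-catalog-style association tables.

The NHGRI catalog export is a tab-separated table with one row per reported
association; a row may list several SNPs (haplotype reports) in one cell.
This module expands such rows into one record per rsid, applies the two
study-level filters used throughout the analysis (a minimum number of
independent GWAS reports per trait, and a per-SNP significance threshold),
and assigns each surviving trait to a disease category from configuration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GwasRecord",
    "FilterPolicy",
    "TraitCategoryMap",
    "ParseReport",
    "read_catalog",
    "filter_traits",
    "assign_categories",
    "write_records",
]

#: closed vocabulary of category labels
ANALYSIS_CATEGORIES = (
    "cardiovascular",
    "metabolic",
    "neurodegenerative",
    "cancer",
    "other",
)
SIDE_CATEGORIES = ("longevity", "non_age_related")
ALL_CATEGORIES = ANALYSIS_CATEGORIES + SIDE_CATEGORIES

#: default column names of the NHGRI catalog export
DEFAULT_COLUMNS = {
    "trait": "DISEASE/TRAIT",
    "study_id": "PUBMEDID",
    "snps": "SNPS",
    "p_value": "P-VALUE",
}

_RSID_RE = re.compile(r"^rs\d+$")


def normalize_trait(label: str) -> str:
    """Trim, collapse internal whitespace and case-fold a trait label."""
    return " ".join(str(label).split()).casefold()


@dataclass(frozen=True)
class GwasRecord:
    """One trait-SNP association after multi-SNP cells have been expanded."""

    trait: str
    study_id: str
    rsid: str
    p_value: float
    category: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if not self.rsid:
            raise ValueError("rsid must be non-empty")


@dataclass(frozen=True)
class FilterPolicy:
    """Trait/SNP inclusion rules.

    min_studies
        Minimum number of distinct study identifiers a trait must have been
        examined in, counted on the unfiltered records for that trait.
    p_max
        Association p-value threshold for a SNP to count as trait-associated.
    strict_less
        If True (default) a SNP survives only with p strictly below p_max.
    """

    min_studies: int = 5
    p_max: float = 1e-5
    strict_less: bool = True

    def __post_init__(self) -> None:
        if self.min_studies < 1:
            raise ValueError("min_studies must be >= 1")
        if not (0.0 < self.p_max < 1.0):
            raise ValueError("p_max must be in (0, 1)")

    def snp_passes(self, p: float) -> bool:
        return p < self.p_max if self.strict_less else p <= self.p_max


@dataclass
class TraitCategoryMap:
    """Mapping from normalized trait label to a disease-category label."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for trait, cat in self.entries.items():
            if cat not in ALL_CATEGORIES:
                raise ValueError(
                    f"unknown category {cat!r} for trait {trait!r}; "
                    f"expected one of {ALL_CATEGORIES}"
                )
            key = normalize_trait(trait)
            if key in normalized and normalized[key] != cat:
                raise ValueError(f"trait {trait!r} mapped to two categories")
            normalized[key] = cat
        self.entries = normalized

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitCategoryMap":
        """Read a two-column ``trait<TAB>category`` file ('#' comments allowed)."""
        entries: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed category-map line: {line!r}")
            entries[parts[0]] = parts[1]
        return cls(entries)

    def lookup(self, trait: str) -> str | None:
        return self.entries.get(normalize_trait(trait))


@dataclass
class ParseReport:
    """Counts of rows/cells dropped while reading a catalog file."""

    n_rows: int = 0
    n_records: int = 0
    bad_p_value: int = 0
    bad_rsid: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


class CatalogSchemaError(ValueError):
    """A required column is missing from the catalog file."""


class EmptyCatalogError(ValueError):
    """The catalog file contains no parsable association rows."""


def read_catalog(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[GwasRecord], ParseReport]:
    """Read a catalog TSV into one :class:`GwasRecord` per (row, rsid).

    Multi-SNP cells are split on ";" and ","; each rsid inherits the row's
    p-value.  Rows with unparsable p-values, and rsids without the ``rs``
    prefix, are skipped and counted in the returned :class:`ParseReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"missing required column(s): {missing}")

    report = ParseReport()
    records: list[GwasRecord] = []
    for _, row in df.iterrows():
        report.n_rows += 1
        try:
            p = float(row[cols["p_value"]])
        except (TypeError, ValueError):
            report.bad_p_value += 1
            continue
        if not (0.0 < p <= 1.0):
            report.bad_p_value += 1
            continue
        snp_cell = str(row[cols["snps"]])
        for token in re.split(r"[;,]", snp_cell):
            rsid = token.strip()
            if not rsid:
                continue
            if not _RSID_RE.match(rsid):
                report.bad_rsid += 1
                continue
            records.append(
                GwasRecord(
                    trait=str(row[cols["trait"]]).strip(),
                    study_id=str(row[cols["study_id"]]).strip(),
                    rsid=rsid,
                    p_value=p,
                )
            )
    report.n_records = len(records)
    if not records:
        raise EmptyCatalogError(f"no parsable association rows in {path}")
    return records, report


def filter_traits(
    records: Iterable[GwasRecord],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[list[GwasRecord], pd.DataFrame]:
    """Apply the study-count and SNP-significance filters.

    A trait survives when it has at least ``policy.min_studies`` distinct
    study identifiers among the *original* records; within surviving traits
    a record survives when its p-value passes the threshold.  Returns the
    surviving records and a per-trait summary frame with distinct study
    counts and surviving distinct-SNP counts (traits with zero surviving
    SNPs are retained in the summary with n_snps = 0).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to filter")

    studies: dict[str, set[str]] = {}
    for rec in records:
        studies.setdefault(normalize_trait(rec.trait), set()).add(rec.study_id)

    surviving: list[GwasRecord] = []
    snps: dict[str, set[str]] = {}
    for rec in records:
        key = normalize_trait(rec.trait)
        if len(studies[key]) < policy.min_studies:
            continue
        snps.setdefault(key, set())
        if not policy.snp_passes(rec.p_value):
            continue
        surviving.append(rec)
        snps[key].add(rec.rsid)

    summary = pd.DataFrame(
        [
            {"trait": t, "n_studies": len(studies[t]), "n_snps": len(snps[t])}
            for t in sorted(snps)
        ],
        columns=["trait", "n_studies", "n_snps"],
    )
    return surviving, summary


def assign_categories(
    records: Iterable[GwasRecord],
    category_map: TraitCategoryMap,
    on_unassigned: str = "warn",
) -> tuple[dict[str, set[str]], list[GwasRecord], dict[str, set[str]]]:
    """Tag records with disease categories.

    Returns ``(category -> trait set, tagged records, side_channel)`` where
    the first mapping covers only the five analysis categories.  Traits
    mapped to ``longevity`` or ``non_age_related`` go to the side channel,
    as do traits absent from the map (under key ``"unassigned"``); nothing
    is silently dropped.

    on_unassigned: ``"strict"`` raises if any trait is missing from the map;
    ``"warn"`` lists them in the side channel.
    """
    if not category_map.entries:
        raise ValueError("category map is empty")
    if on_unassigned not in ("strict", "warn"):
        raise ValueError("on_unassigned must be 'strict' or 'warn'")

    by_category: dict[str, set[str]] = {}
    side: dict[str, set[str]] = {c: set() for c in SIDE_CATEGORIES}
    side["unassigned"] = set()
    tagged: list[GwasRecord] = []
    for rec in records:
        cat = category_map.lookup(rec.trait)
        trait_key = normalize_trait(rec.trait)
        if cat is None:
            side["unassigned"].add(trait_key)
            continue
        if cat in SIDE_CATEGORIES:
            side[cat].add(trait_key)
            continue
        by_category.setdefault(cat, set()).add(trait_key)
        tagged.append(
            GwasRecord(rec.trait, rec.study_id, rec.rsid, rec.p_value, category=cat)
        )
    if side["unassigned"] and on_unassigned == "strict":
        raise ValueError(
            f"traits missing from category map: {sorted(side['unassigned'])}"
        )
    return by_category, tagged, side


def write_records(records: Iterable[GwasRecord], path: str | Path) -> None:
    """Write records as a TSV with trait/study/rsid/p-value/category columns."""
    df = pd.DataFrame(
        [
            {
                "trait": r.trait,
                "study_id": r.study_id,
                "rsid": r.rsid,
                "p_value": r.p_value,
                "category": r.category or "",
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_report(report: ParseReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2), encoding="utf-8")
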