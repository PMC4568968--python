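"""Gene Ontology DAG handling and gene-to-term annotation.

Wraps an OBO 1.2 ontology (parsed with :mod:`obonet`) as a light DAG object
exposing the typed child->parent edges (``is_a``, ``part_of``) used by both
the term-compilation step and the Wang semantic-similarity computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .mapping import CategoryGeneSets

__all__ = [
    "GoDag",
    "AnnotationMap",
    "CategoryTermSets",
    "read_obo",
    "read_annotations",
    "compile_term_sets",
]

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
RELATIONS = ("is_a", "part_of")


@dataclass
class GoDag:
    """Ontology terms plus typed, acyclic child->parent edges.

    parents maps term -> tuple of (parent term, relation); only ``is_a`` and
    ``part_of`` edges participate in analysis.  ``alt_ids`` resolves merged
    secondary identifiers to their primary term.
    """

    terms: dict[str, dict]  # id -> {name, namespace, obsolete}
    parents: dict[str, tuple[tuple[str, str], ...]]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, links in self.parents.items():
            for parent, rel in links:
                if child not in self.terms or parent not in self.terms:
                    raise ValueError(f"dangling edge {child} -> {parent}")
                if rel not in RELATIONS:
                    raise ValueError(f"unsupported relation {rel!r}")
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        self._anc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.terms

    def resolve(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def namespace(self, term: str) -> str:
        return self.terms[self.resolve(term)]["namespace"]

    def is_obsolete(self, term: str) -> bool:
        return bool(self.terms[self.resolve(term)].get("obsolete", False))

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a/part_of ancestors of ``term`` (excluding the term itself)."""
        term = self.resolve(term)
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [p for p, _ in self.parents.get(term, ())]
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(p for p, _ in self.parents.get(t, ()))
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def roots(self) -> set[str]:
        return {
            t
            for t, info in self.terms.items()
            if not self.parents.get(t) and not info.get("obsolete")
        }


@dataclass
class AnnotationMap:
    """gene -> set of GO term ids, validated against a DAG at load time."""

    by_gene: dict[str, set[str]]
    n_dropped_unknown: int = 0
    n_dropped_obsolete: int = 0
    n_dropped_namespace: int = 0
    n_dropped_not: int = 0
    n_dropped_evidence: int = 0

    def terms_for(self, gene: str) -> set[str]:
        return self.by_gene.get(gene, set())


@dataclass
class CategoryTermSets:
    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        union = set().union(*self.sets.values()) if self.sets else set()
        if not self.universe:
            self.universe = union
        elif self.universe != union:
            raise ValueError("universe does not equal union of category term sets")


def read_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2 file into a :class:`GoDag` (cycle-checked)."""
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    terms: dict[str, dict] = {}
    parents: dict[str, tuple[tuple[str, str], ...]] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[node] = {
            "name": data.get("name", node),
            "namespace": data.get("namespace", "biological_process"),
            "obsolete": obsolete,
        }
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
        if obsolete:
            continue  # obsolete terms keep no analysis edges
        links: list[tuple[str, str]] = []
        for _, parent, rel in graph.out_edges(node, keys=True):
            if rel in RELATIONS:
                links.append((parent, rel))
        if links:
            parents[node] = tuple(sorted(links))
    return GoDag(terms=terms, parents=parents, alt_ids=alt_ids)


def read_annotations(
    path: str | Path,
    dag: GoDag,
    namespace_filter: str | None = None,
    exclude_evidence: Iterable[str] = (),
) -> AnnotationMap:
    """Read gene->term annotations (GAF 2.x or 2-column TSV).

    GAF rows with a NOT qualifier are excluded; terms unknown to the DAG or
    obsolete, and terms outside ``namespace_filter`` (if given), are dropped
    with counts.  Raises if nothing survives.
    """
    amap = AnnotationMap(by_gene={})
    exclude_evidence = set(exclude_evidence)
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 15:  # GAF
            gene, qualifier, term, evidence = fields[1], fields[3], fields[4], fields[6]
            if "NOT" in qualifier.split("|"):
                amap.n_dropped_not += 1
                continue
            if evidence in exclude_evidence:
                amap.n_dropped_evidence += 1
                continue
        elif len(fields) == 2:
            gene, term = fields
        else:
            continue
        term = dag.resolve(term)
        if term not in dag.terms:
            amap.n_dropped_unknown += 1
            continue
        if dag.is_obsolete(term):
            amap.n_dropped_obsolete += 1
            continue
        if namespace_filter and dag.namespace(term) != namespace_filter:
            amap.n_dropped_namespace += 1
            continue
        amap.by_gene.setdefault(gene, set()).add(term)
    if not amap.by_gene:
        raise ValueError(f"no surviving annotations in {path}")
    return amap


def compile_term_sets(
    gene_sets: CategoryGeneSets,
    annotations: AnnotationMap,
    dag: GoDag | None = None,
    propagate: bool = False,
    exclude_roots: bool = True,
) -> tuple[CategoryTermSets, dict[str, int]]:
    """Union the GO annotations of each category's genes.

    With ``propagate`` each direct term is replaced by itself plus all of
    its is_a/part_of ancestors; the namespace roots are removed from the
    compiled sets by default (they appear in every gene's closure and carry
    no information).  Returns the term sets and per-category counts of
    unannotated genes.
    """
    if propagate and dag is None:
        raise ValueError("propagation requires the ontology DAG")
    roots = dag.roots() if (dag is not None and exclude_roots) else set()
    sets: dict[str, set[str]] = {}
    unannotated: dict[str, int] = {}
    for cat, genes in gene_sets.sets.items():
        terms: set[str] = set()
        missing = 0
        for gene in genes:
            direct = annotations.terms_for(gene)
            if not direct:
                missing += 1
                continue
            terms |= direct
            if propagate:
                for t in direct:
                    terms |= dag.ancestors(t)
        sets[cat] = terms - roots
        unannotated[cat] = missing
    return CategoryTermSets(sets=sets), unannotated
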