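"""Wang-method GO semantic similarity and the overlap-vs-background test.

The Wang measure scores a term A by the edge-weighted contributions of its
ancestors: S_A(A) = 1 and, moving rootward, S_A(t) = max over children c of
t that lie on a path to A of w(edge) * S_A(c), with w = 0.8 for ``is_a``
and 0.6 for ``part_of`` edges.  The similarity of two terms is the summed
S-values of their common ancestors normalized by the two SV totals:

    sim(A, B) = sum_{t in anc(A) ∩ anc(B)} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

The significance of a term set's internal similarity relative to a
background set is assessed with a one-sided Wilcoxon rank-sum test on the
two vectors of all unordered within-set pairwise similarities (alternative:
overlap stochastically greater).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .ontology import GoDag

__all__ = [
    "EdgeWeights",
    "SemanticValueTable",
    "RankSumResult",
    "WangSimilarity",
    "svalues",
    "term_similarity",
    "pairwise_set_similarities",
    "rank_sum_test",
    "overlap_vs_background_test",
]


@dataclass(frozen=True)
class EdgeWeights:
    """Semantic contribution factors per edge type."""

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self) -> None:
        for w in (self.w_is_a, self.w_part_of):
            if not (0.0 < w < 1.0):
                raise ValueError("edge weights must lie in (0, 1)")

    def of(self, relation: str) -> float:
        return self.w_is_a if relation == "is_a" else self.w_part_of


@dataclass
class SemanticValueTable:
    """S-values of one focal term's ancestor closure (focal included)."""

    focal: str
    s_values: dict[str, float]
    sv_total: float


class WangSimilarity:
    """S-value tables with per-term caching over one DAG + weight setting."""

    def __init__(self, dag: GoDag, weights: EdgeWeights = EdgeWeights()):
        self.dag = dag
        self.weights = weights
        self._tables: dict[str, SemanticValueTable] = {}

    def svalues(self, term: str) -> SemanticValueTable:
        term = self.dag.resolve(term)
        if term not in self.dag.terms:
            raise KeyError(f"unknown term {term!r}")
        if self.dag.is_obsolete(term):
            raise ValueError(f"term {term} is obsolete")
        cached = self._tables.get(term)
        if cached is not None:
            return cached

        # restrict to focal + ancestors, then sweep in reverse topological
        # order (children before parents) taking the max over incoming edges
        nodes = {term} | set(self.dag.ancestors(term))
        indeg = {t: 0 for t in nodes}
        for t in nodes:
            for parent, _ in self.dag.parents.get(t, ()):
                indeg[parent] += 1
        s: dict[str, float] = {term: 1.0}
        ready = [t for t, d in indeg.items() if d == 0]  # only the focal term
        while ready:
            child = ready.pop()
            for parent, rel in self.dag.parents.get(child, ()):
                contrib = self.weights.of(rel) * s[child]
                if contrib > s.get(parent, 0.0):
                    s[parent] = contrib
                indeg[parent] -= 1
                if indeg[parent] == 0:
                    ready.append(parent)
        table = SemanticValueTable(focal=term, s_values=s, sv_total=sum(s.values()))
        self._tables[term] = table
        return table

    def sim(self, a: str, b: str) -> float:
        a, b = self.dag.resolve(a), self.dag.resolve(b)
        if self.dag.namespace(a) != self.dag.namespace(b):
            raise ValueError(
                f"terms {a} and {b} belong to different namespaces "
                "(no shared root, similarity undefined)"
            )
        ta, tb = self.svalues(a), self.svalues(b)
        if len(ta.s_values) > len(tb.s_values):
            ta, tb = tb, ta
        shared = sum(
            sv + tb.s_values[t] for t, sv in ta.s_values.items() if t in tb.s_values
        )
        return shared / (ta.sv_total + tb.sv_total)


def svalues(term: str, dag: GoDag, weights: EdgeWeights = EdgeWeights()) -> SemanticValueTable:
    return WangSimilarity(dag, weights).svalues(term)


def term_similarity(
    a: str, b: str, dag: GoDag, weights: EdgeWeights = EdgeWeights()
) -> float:
    return WangSimilarity(dag, weights).sim(a, b)


def pairwise_set_similarities(
    terms: set[str] | list[str],
    dag: GoDag,
    weights: EdgeWeights = EdgeWeights(),
    engine: WangSimilarity | None = None,
    allow_mixed_namespaces: bool = False,
) -> tuple[np.ndarray, int]:
    """Similarities of all unordered pairs within one term set.

    Pairs are enumerated in lexicographic order.  Cross-namespace pairs are
    fatal unless ``allow_mixed_namespaces``, in which case they are skipped
    and counted in the second return value.
    """
    ordered = sorted(set(terms))
    if len(ordered) < 2:
        raise ValueError("need at least 2 terms for pairwise similarities")
    eng = engine if engine is not None else WangSimilarity(dag, weights)
    values: list[float] = []
    skipped = 0
    for a, b in itertools.combinations(ordered, 2):
        if allow_mixed_namespaces and dag.namespace(a) != dag.namespace(b):
            skipped += 1
            continue
        values.append(eng.sim(a, b))
    return np.asarray(values, dtype=float), skipped


@dataclass
class RankSumResult:
    """One-sided Wilcoxon rank-sum test of overlap vs background similarities."""

    n_overlap: int
    n_background: int
    statistic: float  # rank-sum of the overlap sample
    p_value: float
    method: str  # "exact" | "normal_approx"
    mean_overlap: float
    sd_overlap: float
    mean_background: float
    sd_background: float
    all_tied: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


#: combination-count ceiling for in-repo full enumeration when ties are present
_ENUM_LIMIT = 300_000


def rank_sum_test(
    overlap: np.ndarray, background: np.ndarray, exact_limit: int = 10_000
) -> RankSumResult:
    """One-sided (greater) Wilcoxon rank-sum of two similarity vectors.

    Exact when the pooled sample is small enough: without ties the exact
    distribution of U is used; with ties the permutation distribution of the
    rank-sum is enumerated in full while the number of subsets stays
    tractable.  Otherwise the normal approximation with tie and continuity
    corrections applies.  Two samples with a single shared value are
    degenerate: p = 1 with ``all_tied`` set.
    """
    x = np.asarray(overlap, dtype=float)
    y = np.asarray(background, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    base = dict(
        n_overlap=len(x),
        n_background=len(y),
        statistic=w,
        mean_overlap=float(x.mean()),
        sd_overlap=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        mean_background=float(y.mean()),
        sd_background=float(y.std(ddof=1)) if len(y) > 1 else 0.0,
    )
    if np.unique(pooled).size == 1:
        return RankSumResult(p_value=1.0, method="exact", all_tied=True, **base)

    n = len(pooled)
    has_ties = np.unique(pooled).size < n
    if n <= exact_limit and not has_ties:
        p = float(sps.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue)
        return RankSumResult(p_value=p, method="exact", **base)
    if n <= exact_limit and math.comb(n, len(x)) <= _ENUM_LIMIT:
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n), len(x)):
            total += 1
            if sum(ranks[i] for i in idx) >= w - 1e-9:
                hits += 1
        return RankSumResult(p_value=hits / total, method="exact", **base)
    p = float(sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue)
    return RankSumResult(p_value=p, method="normal_approx", **base)


def overlap_vs_background_test(
    overlap_terms: set[str] | list[str],
    background_terms: set[str] | list[str],
    dag: GoDag,
    weights: EdgeWeights = EdgeWeights(),
    exact_limit: int = 10_000,
    engine: WangSimilarity | None = None,
) -> RankSumResult:
    """Test whether overlap terms are more similar to each other than
    background terms are, via within-set pairwise Wang similarities."""
    if len(set(overlap_terms)) < 2 or len(set(background_terms)) < 2:
        raise ValueError("both term sets must contain at least 2 terms")
    eng = engine if engine is not None else WangSimilarity(dag, weights)
    sims_o, _ = pairwise_set_similarities(overlap_terms, dag, weights, engine=eng)
    sims_b, _ = pairwise_set_similarities(background_terms, dag, weights, engine=eng)
    return rank_sum_test(sims_o, sims_b, exact_limit=exact_limit)
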