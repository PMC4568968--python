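"""Multi-set overlap machinery shared by the gene- and GO-term analyses.

Given per-category item sets this module computes exact-k membership
(items found in exactly k categories), at-least-m shared sets, a pairwise
category similarity matrix, and an agglomerative clustering of categories
on 1 - similarity.  Everything is deterministic: outputs are sorted and
ties break lexicographically on category labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "OverlapResult",
    "SimilarityMatrix",
    "overlap",
    "pairwise_similarity",
    "cluster_categories",
]


@dataclass
class OverlapResult:
    """Membership breakdown of the union of several category item sets."""

    labels: list[str]
    category_count_per_item: dict[str, int]
    exact_k: dict[int, set[str]]
    membership: dict[str, tuple[str, ...]]  # item -> sorted categories holding it

    @property
    def universe(self) -> set[str]:
        return set(self.category_count_per_item)

    def at_least(self, m: int) -> set[str]:
        """Items present in at least m categories."""
        return {i for i, k in self.category_count_per_item.items() if k >= m}

    def shared_fraction(self, m: int | None = None) -> float:
        """|at_least(m)| / |universe| (m defaults to the category count)."""
        if not self.category_count_per_item:
            return 0.0
        m = len(self.labels) if m is None else m
        return len(self.at_least(m)) / len(self.universe)

    def to_frame(self) -> pd.DataFrame:
        """UpSet-style table: item, membership, k — sorted by (-k, item)."""
        rows = [
            {
                "item": item,
                "membership": "|".join(self.membership[item]),
                "k": self.category_count_per_item[item],
            }
            for item in sorted(
                self.category_count_per_item,
                key=lambda i: (-self.category_count_per_item[i], i),
            )
        ]
        return pd.DataFrame(rows, columns=["item", "membership", "k"])


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray
    mode: str  # "shared_over_universe" | "jaccard"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("similarities must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def overlap(sets: dict[str, set[str]]) -> OverlapResult:
    """Exact-k membership decomposition of >= 2 category item sets."""
    if len(sets) < 2:
        raise ValueError("overlap requires at least 2 categories")
    labels = sorted(sets)
    counts: dict[str, int] = {}
    membership: dict[str, tuple[str, ...]] = {}
    for item in set().union(*sets.values()):
        cats = tuple(lab for lab in labels if item in sets[lab])
        counts[item] = len(cats)
        membership[item] = cats
    exact_k = {k: set() for k in range(1, len(labels) + 1)}
    for item, k in counts.items():
        exact_k[k].add(item)
    return OverlapResult(
        labels=labels,
        category_count_per_item=counts,
        exact_k=exact_k,
        membership=membership,
    )


def pairwise_similarity(
    sets: dict[str, set[str]], mode: str = "shared_over_universe"
) -> SimilarityMatrix:
    """Pairwise category similarity.

    ``shared_over_universe``: |A ∩ B| / |union over ALL categories| — the
    "fraction of all genes" normalization; the diagonal is |A| / |universe|.
    ``jaccard``: |A ∩ B| / |A ∪ B| with a unit diagonal.
    """
    if mode not in ("shared_over_universe", "jaccard"):
        raise ValueError(f"unknown similarity mode {mode!r}")
    labels = sorted(sets)
    universe = set().union(*sets.values())
    if not universe:
        raise ValueError("cannot compute similarity over an empty universe")
    n = len(labels)
    values = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            inter = len(sets[a] & sets[b])
            if mode == "shared_over_universe":
                values[i, j] = inter / len(universe)
            else:
                union = len(sets[a] | sets[b])
                values[i, j] = inter / union if union else 0.0
    return SimilarityMatrix(labels=labels, values=values, mode=mode)


def cluster_categories(
    matrix: SimilarityMatrix, method: str = "average"
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of categories on distance = 1 - similarity.

    Returns the scipy linkage array, the leaf order, and a newick string.
    Labels are pre-sorted so equal-distance merges resolve lexicographically.
    """
    if len(matrix.labels) < 2:
        raise ValueError("need at least 2 categories to cluster")
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    newick = _linkage_to_newick(z, matrix.labels)
    leaves = _leaf_order(z, matrix.labels)
    return z, leaves, newick


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    reps: dict[int, str] = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        # branch length = merge height minus child's own merge height
        la = f"{reps[a]}:{h - heights[a]:.6g}"
        lb = f"{reps[b]}:{h - heights[b]:.6g}"
        node = n + step
        first, second = sorted([la, lb])
        reps[node] = f"({first},{second})"
        heights[node] = float(h)
    return reps[n + len(z) - 1] + ";"


def _leaf_order(z: np.ndarray, labels: list[str]) -> list[str]:
    n = len(labels)
    children: dict[int, tuple[int, int]] = {}
    for step, (a, b, _, _) in enumerate(z):
        children[n + step] = (int(a), int(b))

    def walk(node: int) -> list[str]:
        if node < n:
            return [labels[node]]
        a, b = children[node]
        left, right = walk(a), walk(b)
        return left + right if left[0] <= right[0] else right + left

    return walk(n + len(z) - 1)
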