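"""Fisher's combined probability test and hypergeometric GO enrichment.

Fisher's method combines k independent p-values via X = -2 * sum(ln p_i),
which is chi-square distributed with 2k degrees of freedom under the joint
null.  For even degrees of freedom the upper tail has the closed form

    P(chi2_{2k} >= X) = exp(-X/2) * sum_{j=0}^{k-1} (X/2)^j / j!

evaluated here in log space so that combined probabilities far below the
double underflow of the naive product (1e-13 .. 1e-20 and beyond) keep
full relative precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationMap

__all__ = [
    "CombinedTestResult",
    "EnrichmentRow",
    "fisher_combined",
    "hypergeom_enrichment",
    "bh_adjust",
]


@dataclass(frozen=True)
class CombinedTestResult:
    k: int
    statistic: float  # X = -2 sum ln p
    df: int  # 2k
    p_combined: float
    log_p_combined: float  # natural log, exact even when p underflows

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def fisher_combined(p_values) -> CombinedTestResult:
    """Combine independent p-values with Fisher's method."""
    ps = [float(p) for p in p_values]
    if not ps:
        raise ValueError("need at least one p-value")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    k = len(ps)
    x = -2.0 * sum(math.log(p) for p in ps)
    half = x / 2.0
    # log of the even-df chi-square survival series
    if half == 0.0:
        log_p = 0.0
    else:
        js = np.arange(k)
        log_p = -half + logsumexp(js * math.log(half) - gammaln(js + 1))
    log_p = min(log_p, 0.0)
    return CombinedTestResult(
        k=k, statistic=x, df=2 * k, p_combined=math.exp(log_p), log_p_combined=log_p
    )


@dataclass(frozen=True)
class EnrichmentRow:
    """Hypergeometric over-representation of one GO term in a target list."""

    term_id: str
    n_target_annotated: int  # k
    n_target: int  # n
    n_background_annotated: int  # K
    n_background: int  # N
    p_value: float
    q_value: float


def hypergeom_enrichment(
    target: set[str],
    background: set[str],
    annotations: AnnotationMap,
) -> list[EnrichmentRow]:
    """Two-unranked-lists GO enrichment of ``target`` against ``background``.

    For each term annotated to at least one background gene the upper-tail
    hypergeometric probability P(X >= k) of seeing k annotated genes among
    the n target genes, given K of N background genes annotated, is
    computed; q-values are Benjamini-Hochberg over all tested terms.  Rows
    come back sorted by (p, term id).
    """
    if not target <= background:
        raise ValueError("target gene set must be a subset of the background")
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    genes_per_term: dict[str, set[str]] = {}
    for gene in background:
        for term in annotations.terms_for(gene):
            genes_per_term.setdefault(term, set()).add(gene)
    n_bg, n_tg = len(background), len(target)
    terms = sorted(genes_per_term)
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for term in terms:
        annotated = genes_per_term[term]
        k = len(annotated & target)
        big_k = len(annotated)
        p = float(sps.hypergeom.sf(k - 1, n_bg, big_k, n_tg))
        pvals.append(min(p, 1.0))
        rows.append(
            EnrichmentRow(
                term_id=term,
                n_target_annotated=k,
                n_target=n_tg,
                n_background_annotated=big_k,
                n_background=n_bg,
                p_value=min(p, 1.0),
                q_value=math.nan,
            )
        )
    qvals = bh_adjust(pvals) if pvals else []
    rows = [
        EnrichmentRow(
            term_id=r.term_id,
            n_target_annotated=r.n_target_annotated,
            n_target=r.n_target,
            n_background_annotated=r.n_background_annotated,
            n_background=r.n_background,
            p_value=r.p_value,
            q_value=q,
        )
        for r, q in zip(rows, qvals)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if ((ps <= 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(v) for v in q]
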