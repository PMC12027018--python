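"""Hypergeometric gene-set enrichment with Benjamini-Hochberg control.

Shared machinery for functional-term, TF-family, and gene-family enrichment:
for a gene set of size n drawn from a background of N genes, of which K carry
a term, the upper-tail hypergeometric probability of seeing >= k carriers is
the enrichment p-value; p-values are adjusted per gene set and annotation
source by the BH step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import AnnotationTable

DEFAULT_ALPHA = 0.05


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    set_id: str
    term_id: str
    term_label: str
    k: int  # set members carrying the term
    K: int  # background members carrying the term
    n: int  # set size
    N: int  # background size
    p: float
    padj: float

    @property
    def significant(self) -> bool:
        return self.padj < DEFAULT_ALPHA


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed via the stable
    survival function (log-space internally in scipy)."""
    if not (0 <= k <= min(K, n)):
        raise EnrichmentError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N or K < 0 or n < 0:
        raise EnrichmentError(f"need K, n <= N and >= 0; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order and
    capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_set(
    genes: set[str] | frozenset[str],
    annotations: AnnotationTable,
    background: set[str] | frozenset[str],
    alpha: float = DEFAULT_ALPHA,
    set_id: str = "set",
    min_hits: int = 0,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in ``genes``.

    One hypergeometric upper-tail test per term with at least one annotated
    background gene (and, if ``min_hits`` > 0, at least that many carriers in
    the set); BH adjustment across the tested terms. The background should be
    the species' expressed genes — the universe the set was sampled from.
    """
    genes = set(genes)
    background = set(background)
    if not background:
        raise EnrichmentError("background gene set is empty")
    if not genes <= background:
        stray = sorted(genes - background)[:5]
        raise EnrichmentError(f"gene(s) outside the background: {stray}")
    n, N = len(genes), len(background)
    rows: list[tuple[str, int, int]] = []
    skipped: list[str] = []
    for term in sorted(annotations.terms):
        carriers = annotations.genes_with_term(term) & background
        if not carriers:
            skipped.append(term)
            continue
        k = len(carriers & genes)
        if k < min_hits:
            continue
        rows.append((term, k, len(carriers)))
    if skipped:
        import warnings

        warnings.warn(
            f"{len(skipped)} term(s) absent from the background annotation "
            "were skipped",
            stacklevel=2,
        )
    if not rows:
        return []
    pvals = [hypergeom_upper_tail(k, K, n, N) for _, k, K in rows]
    padj = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            set_id=set_id,
            term_id=term,
            term_label=annotations.term_labels.get(term, ""),
            k=k, K=K, n=n, N=N, p=p, padj=float(q),
        )
        for (term, k, K), p, q in zip(rows, pvals, padj)
    ]
    results.sort(key=lambda r: (r.padj, r.p, r.term_id))
    return results


def results_frame(results: list[EnrichmentResult], source: str = "pathway"):
    """Long-format results table (one row per set × term)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "source": source,
                "term_id": r.term_id,
                "term_label": r.term_label,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p": r.p, "padj": r.padj,
                "significant_p": r.p < DEFAULT_ALPHA,
                "significant_fdr": r.padj < DEFAULT_ALPHA,
            }
            for r in results
        ]
    )
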