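"""Mutual-rank co-expression network construction and seed neighborhoods.

A genome-wide Pearson correlation (PCC) matrix is computed over all samples
of a species (log2(TPM+1) by default). Because raw PCC thresholds favour
hub-heavy modules, edges are selected by mutual rank (MR): each gene ranks
its partners by descending PCC, and MR(a, b) = sqrt(rank_a(b) * rank_b(a)).
A pair is retained when its PCC clears a cutoff (by default the 95th
percentile of positive off-diagonal PCC values) and it is either within one
endpoint's top-3 MR partners or has MR <= 30. Seed-gene neighborhoods
(e.g. YABBY transcription factors) are extracted by the global top-PCC
threshold and their gene families tested for hypergeometric enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, enrich_set
from .expression_io import AnnotationTable, ExpressionMatrix

DEFAULT_MR_CUTOFF = 30
DEFAULT_TOP_N = 3
DEFAULT_PCC_QUANTILE = 0.95


class NetworkError(ValueError):
    pass


def pcc_matrix(
    expr: ExpressionMatrix | pd.DataFrame, transform: str = "log2p1"
) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene expression across samples.

    ``transform`` is ``log2p1`` (log2(TPM+1), the default variance
    stabilisation for TPM) or ``none``. Genes constant across samples get
    correlation 0 with every partner; the diagonal is 1.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 3:
        raise NetworkError("need at least 3 samples to estimate correlations")
    if transform == "log2p1":
        X = np.log2(values.to_numpy(dtype=float) + 1.0)
    elif transform == "none":
        X = values.to_numpy(dtype=float)
    else:
        raise NetworkError(f"unknown transform {transform!r}")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def mutual_rank(pcc: pd.DataFrame) -> pd.DataFrame:
    """MR(a, b) = sqrt(rank_a(b) * rank_b(a)).

    rank_g(h) is gene h's ordinal position (1-based) in g's partner list
    sorted by descending PCC, ties broken by ascending partner gene id.
    The diagonal is 0 by convention (no self-edges); off-diagonal MR >= 1.
    """
    arr = pcc.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12):
        raise NetworkError("PCC matrix must be square and symmetric")
    n = arr.shape[0]
    id_order = np.argsort(np.argsort(pcc.index.to_numpy()))  # lexicographic rank of each id
    ranks = np.zeros((n, n))
    for g in range(n):
        partners = np.array([h for h in range(n) if h != g])
        order = np.lexsort((id_order[partners], -arr[g, partners]))
        ranks[g, partners[order]] = np.arange(1, n)
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return pd.DataFrame(mr, index=pcc.index, columns=pcc.columns)


def resolve_pcc_cutoff(pcc: pd.DataFrame, spec) -> float:
    """A numeric cutoff, or ("quantile", q) for the q-quantile of the
    positive off-diagonal PCC values."""
    if isinstance(spec, (int, float)) and not isinstance(spec, bool):
        return float(spec)
    if (
        isinstance(spec, (tuple, list))
        and len(spec) == 2
        and spec[0] == "quantile"
    ):
        q = float(spec[1])
        iu = np.triu_indices_from(pcc.to_numpy(), k=1)
        vals = pcc.to_numpy()[iu]
        pos = vals[vals > 0]
        if pos.size == 0:
            raise NetworkError("no positive off-diagonal PCC values")
        return float(np.quantile(pos, q))
    raise NetworkError(
        f"pcc cutoff must be a number or ('quantile', q); got {spec!r}"
    )


@dataclass
class CoexpressionNetwork:
    """Retained co-expression edges with their PCC, MR and retention reason."""

    edges: pd.DataFrame  # columns gene_a, gene_b, pcc, mr, reason
    pcc_cutoff: float
    mr_cutoff: float
    top_n: int
    genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    def graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, pcc=row.pcc, mr=row.mr,
                       reason=row.reason)
        return g

    def neighbors(self, gene: str) -> frozenset[str]:
        e = self.edges
        out = set(e.loc[e["gene_a"] == gene, "gene_b"])
        out |= set(e.loc[e["gene_b"] == gene, "gene_a"])
        return frozenset(out)


def _top_mr_partners(mr: np.ndarray, ids: np.ndarray, top_n: int) -> list[set[int]]:
    """Indices of each gene's top_n smallest-MR partners (ties by id)."""
    n = mr.shape[0]
    id_order = np.argsort(np.argsort(ids))
    tops: list[set[int]] = []
    for g in range(n):
        partners = np.array([h for h in range(n) if h != g])
        order = np.lexsort((id_order[partners], mr[g, partners]))
        tops.append(set(partners[order[:top_n]].tolist()))
    return tops


def build_network(
    pcc: pd.DataFrame,
    mr: pd.DataFrame,
    pcc_cutoff=("quantile", DEFAULT_PCC_QUANTILE),
    mr_cutoff: float = DEFAULT_MR_CUTOFF,
    top_n: int = DEFAULT_TOP_N,
    gate: str = "conjunctive",
) -> CoexpressionNetwork:
    """Retain edge (a, b) iff PCC >= cutoff AND (b in a's top_n MR partners
    OR a in b's OR MR <= mr_cutoff).

    ``gate="union"`` relaxes the conjunction: an edge passes on either the
    PCC gate alone or the MR condition alone.
    """
    if gate not in ("conjunctive", "union"):
        raise NetworkError(f"unknown gate {gate!r}")
    cutoff = resolve_pcc_cutoff(pcc, pcc_cutoff)
    ids = pcc.index.to_numpy()
    P, M = pcc.to_numpy(), mr.to_numpy()
    n = len(ids)
    tops = _top_mr_partners(M, ids, top_n)
    T = np.zeros((n, n), dtype=bool)
    for g, partners in enumerate(tops):
        T[g, list(partners)] = True
    in_top = T | T.T
    mr_ok = in_top | (M <= mr_cutoff)
    np.fill_diagonal(mr_ok, False)
    pcc_ok = P >= cutoff
    keep = (pcc_ok & mr_ok) if gate == "conjunctive" else (pcc_ok | mr_ok)
    np.fill_diagonal(keep, False)
    ia, ib = np.where(np.triu(keep, k=1))
    edges = pd.DataFrame(
        {
            "gene_a": ids[ia],
            "gene_b": ids[ib],
            "pcc": P[ia, ib],
            "mr": M[ia, ib],
            "reason": np.where(in_top[ia, ib], "top3", "mr_le_cutoff"),
        }
    )
    return CoexpressionNetwork(
        edges, cutoff, mr_cutoff, top_n, genes=list(ids)
    )


def seed_neighborhood(
    pcc: pd.DataFrame,
    seeds: list[str],
    pcc_quantile: float = DEFAULT_PCC_QUANTILE,
) -> tuple[dict[str, frozenset[str]], frozenset[str], float]:
    """Partners of each seed gene at the global top-PCC threshold.

    The threshold is the ``pcc_quantile`` quantile of the positive
    off-diagonal PCC values over all gene pairs; a partner is any non-self
    gene with PCC >= threshold. Returns (per-seed partner sets, union of
    non-seed partners, threshold).
    """
    unknown = [s for s in seeds if s not in pcc.index]
    if unknown:
        raise NetworkError(f"unknown seed gene(s): {unknown}")
    thr = resolve_pcc_cutoff(pcc, ("quantile", pcc_quantile))
    per_seed: dict[str, frozenset[str]] = {}
    for seed in seeds:
        row = pcc.loc[seed].drop(labels=[seed])
        per_seed[seed] = frozenset(row.index[row >= thr])
    union = frozenset().union(*per_seed.values()) - frozenset(seeds)
    return per_seed, union, thr


def family_enrichment(
    partners: frozenset[str] | set[str],
    families: AnnotationTable,
    background: frozenset[str] | set[str],
    set_id: str = "all",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of gene families among network partners
    (only families with at least one partner are tested; BH across them)."""
    return enrich_set(
        set(partners), families, set(background), set_id=set_id, min_hits=1
    )
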