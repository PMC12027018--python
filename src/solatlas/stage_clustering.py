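"""Two-species developmental-stage expression clustering.

The flower/fruit-specific genes of two species are profiled over a shared,
ordered set of conditions (vegetative organs followed by the
flower-to-mature-fruit series), z-scored per gene, stacked into one matrix,
and cut into k clusters by Ward-linkage agglomerative clustering on
Euclidean distance. Clusters are relabelled I..k by the condition at which
their centroid peaks, so labels are comparable across runs, and cross-species
cluster correspondence is read off a k × k Jaccard matrix over orthogroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .cross_species import OrthologSet, jaccard, project_to_orthogroups
from .expression_io import ExpressionMatrix
from .specificity import OrganSpecificSet

#: Default number of stage clusters.
DEFAULT_K = 6

#: Default shared condition order: three vegetative organs, then the
#: flower-to-mature-fruit series (young fruit YF, green fruit MG, breaker
#: red BR, mature fruit MF, two periods each).
DEFAULT_CONDITIONS: tuple[str, ...] = (
    "root", "stem", "leaf",
    "flower_bud", "open_flower",
    "YF1", "YF2", "MG1", "MG2", "BR1", "BR2", "MF1", "MF2",
)


class StageError(ValueError):
    pass


@dataclass
class StageProfileMatrix:
    """(species, gene) × condition matrix of per-gene z-scored mean TPM."""

    values: pd.DataFrame  # MultiIndex (species, gene) rows

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def species(self) -> list[str]:
        return sorted(self.values.index.get_level_values(0).unique())


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k, ordered by centroid peak) and memberships."""

    labels: pd.Series  # MultiIndex (species, gene) -> int
    membership: pd.Series  # same index -> [0, 1]
    centroids: pd.DataFrame  # cluster -> condition means (z-scale)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def genes_of(self, species: str, cluster: int) -> frozenset[str]:
        mask = (self.labels == cluster) & (
            self.labels.index.get_level_values(0) == species
        )
        return frozenset(self.labels.index.get_level_values(1)[mask])


def _condition_means(
    expr: ExpressionMatrix, genes: frozenset[str], conditions: tuple[str, ...]
) -> pd.DataFrame:
    """Mean TPM per condition; a sample's condition is its stage label when
    set, otherwise its organ."""
    meta = expr.samples.loc[list(expr.values.columns)]
    cond = meta["stage"].where(meta["stage"].astype(str) != "", meta["organ"])
    unknown = sorted(set(cond) - set(conditions))
    if unknown:
        raise StageError(
            f"sample condition(s) {unknown[:5]} not in the stage map; "
            "extend the condition list or relabel the samples"
        )
    present = [g for g in expr.gene_ids if g in genes]
    block = expr.values.loc[present]
    means = block.T.groupby(cond.values).mean().T
    missing = sorted(set(conditions) - set(means.columns))
    if missing:
        raise StageError(f"condition(s) with no samples: {missing[:5]}")
    return means[list(conditions)]


def build_stage_matrix(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    set_a: OrganSpecificSet,
    set_b: OrganSpecificSet,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
) -> StageProfileMatrix:
    """Average replicates per condition, z-score each gene across conditions,
    and stack the two species' flower/fruit-specific genes into one matrix.

    Genes with a constant profile (zero variance across conditions) carry no
    shape information and are dropped with a warning.
    """
    frames = []
    dropped: list[str] = []
    for expr, gene_set in ((expr_a, set_a), (expr_b, set_b)):
        means = _condition_means(expr, gene_set.genes, conditions)
        mu = means.mean(axis=1)
        sd = means.std(axis=1, ddof=0)
        const = sd == 0
        if const.any():
            dropped += [f"{gene_set.species}:{g}" for g in means.index[const]]
            means = means.loc[~const]
            mu, sd = mu.loc[~const], sd.loc[~const]
        z = means.sub(mu, axis=0).div(sd, axis=0)
        z.index = pd.MultiIndex.from_product(
            [[gene_set.species], z.index], names=["species", "gene_id"]
        )
        frames.append(z)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} constant-profile gene(s): {dropped[:5]}",
            stacklevel=2,
        )
    return StageProfileMatrix(pd.concat(frames))


def cluster_stages(matrix: StageProfileMatrix, k: int = DEFAULT_K) -> ClusterAssignment:
    """Ward/Euclidean agglomerative clustering of the stacked z-profiles,
    cut to exactly k clusters.

    Deterministic: agglomerative clustering has no random initialisation.
    Cluster ids are reassigned 1..k by the position of each centroid's peak
    along the condition order (ties by raw-label order); membership is the
    Pearson correlation of a gene's profile with its cluster centroid,
    floored at 0.
    """
    if k < 2:
        raise StageError("k must be >= 2")
    n = len(matrix.values)
    if k > n:
        raise StageError(f"k={k} exceeds the number of profiles ({n})")
    X = matrix.values.to_numpy()
    raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    centroids = np.vstack([X[raw == c].mean(axis=0) for c in range(k)])
    peak = centroids.argmax(axis=1)
    order = np.lexsort((np.arange(k), peak))  # peak position, then raw label
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=matrix.values.index,
                       name="cluster")
    cent = pd.DataFrame(
        centroids[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=matrix.values.columns,
    )
    cent_arr = cent.to_numpy()
    member = np.empty(n)
    for i in range(n):
        c = cent_arr[labels.iloc[i] - 1]
        r = np.corrcoef(X[i], c)[0, 1]
        member[i] = max(0.0, r) if np.isfinite(r) else 0.0
    membership = pd.Series(member, index=matrix.values.index, name="membership")
    return ClusterAssignment(labels, membership, cent)


def cluster_jsc(
    assign: ClusterAssignment,
    orthos: OrthologSet,
    species_a: str,
    species_b: str,
    restrict_universe: bool = True,
) -> pd.DataFrame:
    """k × k matrix whose (i, j) entry is the orthogroup-level Jaccard
    similarity between species-A genes of cluster i and species-B genes of
    cluster j. Not symmetric in general."""
    k = assign.k
    out = np.zeros((k, k))
    proj = {}
    for sp, partner in ((species_a, species_b), (species_b, species_a)):
        for c in range(1, k + 1):
            genes = assign.genes_of(sp, c)
            if not genes:
                warnings.warn(
                    f"empty cluster {c} for species {sp}; JSC row/col is 0",
                    stacklevel=2,
                )
                proj[(sp, c)] = frozenset()
                continue
            proj[(sp, c)], _ = project_to_orthogroups(
                genes, orthos, partner_species=partner, species=sp,
                restrict_universe=restrict_universe,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-vs-empty Jaccard
        for i in range(1, k + 1):
            for j in range(1, k + 1):
                out[i - 1, j - 1] = jaccard(
                    proj[(species_a, i)], proj[(species_b, j)]
                )
    labels = [f"cluster_{c}" for c in range(1, k + 1)]
    return pd.DataFrame(out, index=labels, columns=labels)


def assignment_frame(assign: ClusterAssignment) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "species": assign.labels.index.get_level_values(0),
            "gene_id": assign.labels.index.get_level_values(1),
            "cluster": assign.labels.to_numpy(),
            "membership": assign.membership.to_numpy(),
        }
    )
    return out
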