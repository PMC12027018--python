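"""Cross-species conservation of organ-specific expression.

Syntenic ortholog pair files (two-column TSV per species pair) are merged
into an undirected graph whose connected components are the orthogroups —
the unit on which cross-species set overlap is measured. An organ-specific
gene set is projected onto orthogroup ids (restricted to orthogroups that
also contain a gene of the partner species, so lineage-specific genes cannot
deflate similarity), and conservation is quantified by the Jaccard
similarity coefficient (JSC) between projected sets, with same-organ versus
cross-organ JSC distributions compared by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .specificity import OrganSpecificSet

#: Largest per-group size at which the rank-sum test is computed exactly.
EXACT_RANKSUM_MAX_N = 20


class OrthologyError(ValueError):
    pass


@dataclass
class OrthologSet:
    """Syntenic pairs plus the orthogroup partition they induce.

    Orthogroups are the connected components of the undirected pair graph;
    each carries a deterministic id — the lexicographically smallest member
    gene id.
    """

    species_of: dict[str, str]  # gene -> species
    orthogroup_of: dict[str, str]  # gene -> orthogroup id
    groups: dict[str, frozenset[str]]  # orthogroup id -> member genes
    pairs: frozenset[frozenset[str]]

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.species_of.values())

    def group_species(self, og_id: str) -> frozenset[str]:
        return frozenset(self.species_of[g] for g in self.groups[og_id])


def build_orthogroups(
    pair_tables: list[tuple[str, str, pd.DataFrame]],
) -> OrthologSet:
    """Build orthogroups from per-species-pair two-column gene-pair tables.

    ``pair_tables`` holds (species_a, species_b, frame) triples where the
    frame's first column lists species-a gene ids and the second species-b
    gene ids. Many-to-many pairs are supported; a gene id appearing under two
    different species labels is an error.
    """
    graph = nx.Graph()
    species_of: dict[str, str] = {}
    pairs: set[frozenset[str]] = set()
    for species_a, species_b, tab in pair_tables:
        if tab.shape[1] < 2:
            raise OrthologyError("pair table needs two gene-id columns")
        if len(tab) == 0:
            warnings.warn(
                f"empty ortholog pair table for {species_a}-{species_b}",
                stacklevel=2,
            )
            continue
        for ga, gb in zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1].astype(str)):
            for gene, sp in ((ga, species_a), (gb, species_b)):
                prior = species_of.setdefault(gene, sp)
                if prior != sp:
                    raise OrthologyError(
                        f"gene id {gene!r} appears under species {prior!r} "
                        f"and {sp!r}"
                    )
            graph.add_edge(ga, gb)
            pairs.add(frozenset((ga, gb)))
    orthogroup_of: dict[str, str] = {}
    groups: dict[str, frozenset[str]] = {}
    for component in nx.connected_components(graph):
        og_id = min(component)
        groups[og_id] = frozenset(component)
        for gene in component:
            orthogroup_of[gene] = og_id
    return OrthologSet(species_of, orthogroup_of, groups, frozenset(pairs))


def load_ortholog_manifest(manifest_path) -> OrthologSet:
    """Read a manifest TSV (file_path, species_a, species_b) of pair files."""
    import os

    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for col in ("file_path", "species_a", "species_b"):
        if col not in manifest.columns:
            raise OrthologyError(f"ortholog manifest lacks column {col!r}")
    base = os.path.dirname(os.fspath(manifest_path))
    tables = []
    for row in manifest.itertuples(index=False):
        path = row.file_path
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        tab = pd.read_csv(path, sep="\t", dtype=str)
        tables.append((row.species_a, row.species_b, tab))
    return build_orthogroups(tables)


def project_to_orthogroups(
    genes: OrganSpecificSet | frozenset[str] | set[str],
    orthos: OrthologSet,
    partner_species: str,
    species: str | None = None,
    restrict_universe: bool = True,
) -> tuple[frozenset[str], int]:
    """Map a gene set to the orthogroup ids it hits.

    Returns (orthogroup ids, number of genes dropped for lacking any
    orthogroup). With ``restrict_universe`` (default) only orthogroups that
    contain at least one gene of ``partner_species`` are kept, so both sides
    of a JSC comparison live in the same comparable universe.
    """
    if isinstance(genes, OrganSpecificSet):
        species = genes.species
        gene_ids = genes.genes
    else:
        gene_ids = frozenset(genes)
    if species is not None and species not in orthos.species | {species}:
        raise OrthologyError(f"species {species!r} not present in orthologs")
    if partner_species not in orthos.species:
        raise OrthologyError(
            f"partner species {partner_species!r} not present in orthologs"
        )
    ids: set[str] = set()
    dropped = 0
    for gene in gene_ids:
        og = orthos.orthogroup_of.get(gene)
        if og is None:
            dropped += 1
            continue
        if restrict_universe and partner_species not in orthos.group_species(og):
            continue
        ids.add(og)
    return frozenset(ids), dropped


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; 0 (with a warning) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class SimilarityRecord:
    species_a: str
    species_b: str
    organ_a: str
    organ_b: str
    fraction: float
    jsc: float
    n_intersection: int
    n_union: int
    n_dropped_a: int = 0
    n_dropped_b: int = 0


def pairwise_similarity(
    sets_a: list[OrganSpecificSet],
    sets_b: list[OrganSpecificSet],
    orthos: OrthologSet,
    restrict_universe: bool = True,
) -> list[SimilarityRecord]:
    """JSC between every organ set of species A and every organ set of B,
    at each threshold fraction present in both."""
    records: list[SimilarityRecord] = []
    for sa in sets_a:
        proj_a, drop_a = project_to_orthogroups(
            sa, orthos, partner_species=sets_b[0].species,
            restrict_universe=restrict_universe,
        )
        for sb in sets_b:
            if sb.fraction != sa.fraction:
                continue
            proj_b, drop_b = project_to_orthogroups(
                sb, orthos, partner_species=sa.species,
                restrict_universe=restrict_universe,
            )
            inter = proj_a & proj_b
            union = proj_a | proj_b
            records.append(
                SimilarityRecord(
                    sa.species, sb.species, sa.organ, sb.organ, sa.fraction,
                    jsc=len(inter) / len(union) if union else 0.0,
                    n_intersection=len(inter), n_union=len(union),
                    n_dropped_a=drop_a, n_dropped_b=drop_b,
                )
            )
    return records


def similarity_frame(records: list[SimilarityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class RankSumSummary:
    organ: str
    statistic: float
    pvalue: float
    n_same: int
    n_cross: int
    method: str  # "exact" or "asymptotic"


def compare_same_vs_cross(
    records: list[SimilarityRecord],
    fraction: float | None = None,
    per_organ: bool = True,
) -> list[RankSumSummary]:
    """Rank-sum test of same-organ vs cross-organ JSC values.

    Per organ by default; with ``per_organ=False`` all organs are pooled
    into a single test (useful when few species pairs are available).
    Exact two-sided Mann-Whitney p when both groups have at most 20 records,
    otherwise the normal approximation with mid-rank tie correction.
    """
    if fraction is not None:
        records = [r for r in records if r.fraction == fraction]
    organs = sorted({r.organ_a for r in records}) if per_organ else ["all"]
    out: list[RankSumSummary] = []
    for organ in organs:
        sub = records if organ == "all" else [
            r for r in records if r.organ_a == organ
        ]
        same = [r.jsc for r in sub if r.organ_a == r.organ_b]
        cross = [r.jsc for r in sub if r.organ_a != r.organ_b]
        if len(same) < 2 or len(cross) < 2:
            raise OrthologyError(
                f"organ {organ!r}: need >= 2 same-organ and >= 2 cross-organ "
                "records for the rank-sum test"
            )
        exact = max(len(same), len(cross)) <= EXACT_RANKSUM_MAX_N
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns on exact-with-ties
            res = stats.mannwhitneyu(
                same, cross, alternative="two-sided",
                method="exact" if exact else "asymptotic",
            )
        out.append(
            RankSumSummary(
                organ, float(res.statistic), float(res.pvalue),
                len(same), len(cross), "exact" if exact else "asymptotic",
            )
        )
    return out
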