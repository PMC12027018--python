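"""Organ-specificity scoring (SPM) and organ-specific gene calling.

The specificity measure of gene *g* in organ *o* is its mean expression in
*o* divided by the sum of its mean expressions across all organs, so each
gene's SPM vector lies on the simplex: 0 means no expression in the organ,
1 exclusive expression. Organ-specific genes are called by pooling each
gene's maximum SPM within a species and thresholding at the top-k% quantile
of that pooled distribution; a called gene is assigned to its argmax organ,
so the per-organ sets at a given threshold are disjoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import OrganProfile

#: Quantile fractions at which organ-specific sets are called.
DEFAULT_FRACTIONS: tuple[float, ...] = (0.02, 0.05, 0.10, 0.20)


class SpecificityError(ValueError):
    pass


@dataclass
class SpecificityTable:
    """Per-gene SPM vectors with the argmax organ and maximum SPM."""

    spm: pd.DataFrame  # genes × organs, rows sum to 1
    argmax_organ: pd.Series  # gene -> organ label
    max_spm: pd.Series  # gene -> max SPM

    @property
    def gene_ids(self) -> list[str]:
        return list(self.spm.index)

    @property
    def organ_ids(self) -> list[str]:
        return list(self.spm.columns)


@dataclass(frozen=True)
class OrganSpecificSet:
    """Genes called specific to one organ of one species at one threshold."""

    species: str
    organ: str
    fraction: float
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def compute_spm(profile: OrganProfile) -> SpecificityTable:
    """Row-normalise an organ profile into SPM scores.

    Genes with zero total expression are rejected: they carry no specificity
    information and must be removed by the expressed-gene filter upstream.
    Argmax ties break to the first organ in the profile's column order.
    """
    vals = profile.values
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        dead = totals.index[totals == 0].tolist()
        raise SpecificityError(
            f"gene(s) with all-zero organ means: {dead[:5]}; filter expressed "
            "genes first"
        )
    spm = vals.div(totals, axis=0)
    # np.argmax takes the first maximum, which is the canonical-order tie-break
    arg_idx = np.argmax(spm.to_numpy(), axis=1)
    argmax = pd.Series(
        [spm.columns[i] for i in arg_idx], index=spm.index, name="argmax_organ"
    )
    return SpecificityTable(spm, argmax, spm.max(axis=1).rename("max_spm"))


def specificity_threshold(max_spm: pd.Series, fraction: float) -> float:
    """Nearest-rank top-``fraction`` cut on the pooled max-SPM distribution."""
    if not 0 < fraction <= 1:
        raise SpecificityError(f"fraction must be in (0, 1], got {fraction}")
    ordered = np.sort(max_spm.to_numpy())[::-1]
    k = max(1, math.ceil(fraction * len(ordered)))
    return float(ordered[k - 1])


def call_specific(
    table: SpecificityTable,
    species: str,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
) -> list[OrganSpecificSet]:
    """Call organ-specific genes at each top-k% threshold.

    The threshold at fraction *f* is the (1−f) quantile (nearest rank) of the
    pooled per-gene maximum SPM; a gene is specific iff its max SPM reaches
    the threshold, and is assigned to its argmax organ. Ties exactly at the
    cut are all included, so a set may slightly exceed k% of genes.
    """
    sets: list[OrganSpecificSet] = []
    for fraction in fractions:
        thr = specificity_threshold(table.max_spm, fraction)
        called = table.max_spm.index[table.max_spm >= thr]
        by_organ = table.argmax_organ.loc[called]
        for organ in table.organ_ids:
            genes = frozenset(by_organ.index[by_organ == organ])
            sets.append(OrganSpecificSet(species, organ, fraction, genes))
    return sets


def organ_share(sets: list[OrganSpecificSet]) -> dict[str, float]:
    """Fraction of all organ-specific genes attributed to each organ.

    All sets must come from one species at one threshold; the shares sum to 1.
    """
    if len({(s.species, s.fraction) for s in sets}) != 1:
        raise SpecificityError(
            "organ_share expects sets from a single species and threshold"
        )
    sizes = {s.organ: len(s.genes) for s in sets}
    total = sum(sizes.values())
    if total == 0:
        raise SpecificityError("no organ-specific genes in any set")
    return {organ: size / total for organ, size in sizes.items()}


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_gene_sets_gmt(sets: list[OrganSpecificSet], path) -> None:
    """GMT-style lines: SPECIES|ORGAN|TOPk<TAB>description<TAB>gene..."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            name = f"{s.species}|{s.organ}|TOP{s.fraction:g}"
            desc = (
                f"{s.organ}-specific genes of {s.species} at the top "
                f"{100 * s.fraction:g}% SPM threshold"
            )
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{name}\t{desc}\t{genes}\n".rstrip() + "\n")


def write_gene_sets_long(
    sets: list[OrganSpecificSet], table: SpecificityTable, path
) -> None:
    rows = [
        (s.species, s.organ, s.fraction, g, float(table.spm.loc[g, s.organ]))
        for s in sets
        for g in sorted(s.genes)
    ]
    pd.DataFrame(
        rows, columns=["species", "organ", "fraction", "gene_id", "spm"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_sets_long(path) -> list[OrganSpecificSet]:
    tab = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "species": str})
    sets = []
    for (species, organ, fraction), grp in tab.groupby(
        ["species", "organ", "fraction"], sort=True
    ):
        sets.append(
            OrganSpecificSet(
                str(species), str(organ), float(fraction),
                frozenset(grp["gene_id"]),
            )
        )
    return sets
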