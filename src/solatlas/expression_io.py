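"""Tabular expression I/O, TPM conversion, and per-organ profile construction.

The pipeline works on bulk expression atlases: a genes × samples TPM matrix
per species, with a sample-metadata table assigning each sample to an organ
(root, stem, leaf, flower, fruit), an optional developmental-stage label, and
a replicate index. Downstream analyses operate on per-organ mean profiles in
which flower and fruit samples are merged into a single reproductive
"flower/fruit" organ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default organ vocabulary for sample metadata.
DEFAULT_ORGANS: tuple[str, ...] = ("root", "stem", "leaf", "flower", "fruit")

#: Label of the merged reproductive organ.
FLOWER_FRUIT: str = "flower/fruit"

#: Canonical column order for organ profiles.
CANONICAL_ORGAN_ORDER: tuple[str, ...] = (
    "root",
    "stem",
    "leaf",
    FLOWER_FRUIT,
    "flower",
    "fruit",
)

#: Expressed-gene TPM threshold (strictly greater than).
DEFAULT_EXPRESSED_TPM: float = 2.0

METADATA_COLUMNS = ("sample_id", "organ", "stage", "replicate")


class ExpressionError(ValueError):
    """Raised for malformed expression matrices or metadata."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × samples TPM matrix with per-sample metadata.

    Parameters
    ----------
    values
        Non-negative genes × samples frame; index = gene ids, columns =
        sample ids.
    samples
        Metadata indexed by sample id with columns ``organ``, ``stage``
        (free string, may be empty) and ``replicate`` (positive int).
    organ_vocabulary
        Accepted organ labels; defaults to the five-organ scheme.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    organ_vocabulary: tuple[str, ...] = DEFAULT_ORGANS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ExpressionError(
                f"sample(s) missing from metadata: {missing[:5]}"
            )
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ExpressionError("expression values must be numeric")
        if np.isnan(vals).any():
            raise ExpressionError("expression matrix contains missing values")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ExpressionError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        organs = self.samples.loc[list(self.values.columns), "organ"]
        if organs.isna().any() or (organs == "").any():
            bad = organs.index[organs.isna() | (organs == "")].tolist()
            raise ExpressionError(f"sample(s) without organ label: {bad[:5]}")
        unknown = sorted(set(organs) - set(self.organ_vocabulary))
        if unknown:
            raise ExpressionError(
                f"unknown organ label(s) {unknown}; declare them via "
                "organ_vocabulary if intended"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def organ_of(self, sample_id: str) -> str:
        return str(self.samples.loc[sample_id, "organ"])


@dataclass
class OrganProfile:
    """Genes × organs matrix of mean TPM (post replicate/stage averaging)."""

    values: pd.DataFrame  # genes × organs

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def organ_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AnnotationTable:
    """gene id → set of term ids, with a term → human-readable label map."""

    gene_to_terms: dict[str, frozenset[str]]
    term_labels: dict[str, str] = field(default_factory=dict)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def genes_with_term(self, term: str) -> frozenset[str]:
        return frozenset(
            g for g, ts in self.gene_to_terms.items() if term in ts
        )

    @property
    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return frozenset(out)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path,
    metadata_path,
    organ_vocabulary: tuple[str, ...] = DEFAULT_ORGANS,
) -> ExpressionMatrix:
    """Read an expression TSV (gene_id + one column per sample) and its
    sample-metadata TSV (sample_id, organ, stage, replicate)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(raw.index, "gene")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ExpressionError(
            f"non-numeric expression value {raw.iat[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    meta = read_sample_metadata(metadata_path)
    return ExpressionMatrix(values.astype(float), meta, organ_vocabulary)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "organ": str, "stage": str}
    )
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ExpressionError(f"metadata lacks column(s): {sorted(missing)}")
    _check_unique(pd.Index(meta["sample_id"]), "sample")
    meta = meta.set_index("sample_id")
    meta["stage"] = meta["stage"].fillna("")
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise ExpressionError("replicate indices must be positive integers")
    return meta


def write_expression(expr: ExpressionMatrix, path, metadata_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    expr.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_annotations(path) -> AnnotationTable:
    """Read a gene→term annotation TSV (gene_id, term_id, term_label)."""
    tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("gene_id", "term_id"):
        if col not in tab.columns:
            raise ExpressionError(f"annotation table lacks column {col!r}")
    gene_to_terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for row in tab.itertuples(index=False):
        gene_to_terms.setdefault(row.gene_id, set()).add(row.term_id)
        label = getattr(row, "term_label", "")
        if label:
            labels[row.term_id] = label
    return AnnotationTable(
        {g: frozenset(ts) for g, ts in gene_to_terms.items()}, labels
    )


def write_annotations(ann: AnnotationTable, path) -> None:
    rows = [
        (g, t, ann.term_labels.get(t, ""))
        for g in sorted(ann.gene_to_terms)
        for t in sorted(ann.gene_to_terms[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id", "term_label"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def counts_to_tpm(
    counts: pd.DataFrame,
    gene_lengths_kb: pd.Series,
    samples: pd.DataFrame | None = None,
    organ_vocabulary: tuple[str, ...] = DEFAULT_ORGANS,
) -> ExpressionMatrix | pd.DataFrame:
    """Convert raw counts to TPM.

    Per sample: rate_g = count_g / length_g (length in kilobases), then
    TPM_g = rate_g / sum_h rate_h × 1e6, so each sample column with any
    nonzero count sums to one million.

    Returns an :class:`ExpressionMatrix` when ``samples`` metadata is given,
    otherwise the bare TPM frame.
    """
    lengths = gene_lengths_kb.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ExpressionError(f"missing gene length(s): {missing[:5]}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ExpressionError(f"non-positive gene length(s): {bad[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ExpressionError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    zero_cols = total[total == 0].index.tolist()
    if zero_cols:
        warnings.warn(
            f"all-zero count column(s) {zero_cols}; TPM set to zero",
            stacklevel=2,
        )
    tpm = rate.div(total.replace(0.0, np.nan), axis=1).fillna(0.0) * 1e6
    if samples is None:
        return tpm
    return ExpressionMatrix(tpm, samples, organ_vocabulary)


def collapse_to_organs(
    expr: ExpressionMatrix,
    merge_flower_fruit: bool = True,
    stage_weighted: bool = False,
) -> OrganProfile:
    """Average samples into one column per organ.

    With ``merge_flower_fruit`` (default), flower and fruit samples are pooled
    into a single "flower/fruit" group before averaging. By default every
    sample of an organ carries equal weight (flat mean over replicates and
    stages); ``stage_weighted`` instead averages per-stage means, giving each
    stage equal weight regardless of its replicate count.
    """
    organs = expr.samples.loc[list(expr.values.columns), "organ"].astype(str)
    if merge_flower_fruit:
        organs = organs.replace({"flower": FLOWER_FRUIT, "fruit": FLOWER_FRUIT})
    cols: dict[str, pd.Series] = {}
    for organ in organs.unique():
        members = organs.index[organs == organ]
        block = expr.values[members]
        if stage_weighted:
            stages = expr.samples.loc[members, "stage"]
            per_stage = block.T.groupby(stages.values).mean()
            cols[organ] = per_stage.mean(axis=0)
        else:
            cols[organ] = block.mean(axis=1)
    order = [o for o in CANONICAL_ORGAN_ORDER if o in cols]
    order += [o for o in cols if o not in order]
    vocab = set(expr.organ_vocabulary) | ({FLOWER_FRUIT} if merge_flower_fruit else set())
    absent = sorted((vocab - {"flower", "fruit"} if merge_flower_fruit else vocab) - set(cols))
    if absent:
        warnings.warn(f"organ(s) with zero samples omitted: {absent}", stacklevel=2)
    return OrganProfile(pd.DataFrame(cols)[order])


def filter_expressed(
    profile: OrganProfile, threshold: float = DEFAULT_EXPRESSED_TPM
) -> OrganProfile:
    """Keep genes whose maximum organ mean is strictly greater than
    ``threshold`` TPM; gene order is preserved."""
    if threshold < 0:
        raise ExpressionError("threshold must be non-negative")
    keep = profile.values.max(axis=1) > threshold
    if not keep.any():
        raise ExpressionError(
            f"no gene exceeds {threshold} TPM in any organ; review the "
            "threshold or the input units"
        )
    return OrganProfile(profile.values.loc[keep])
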