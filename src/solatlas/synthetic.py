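"""Synthetic multi-species expression atlases with known ground truth.

The generator emulates the statistical structure of a Solanaceae-style
multi-organ bulk atlas so every pipeline stage can be exercised end to end
without sequencing data:

* a shared log-normal baseline per orthogroup, inherited by orthologous
  genes in every species;
* planted organ-specific genes receiving a multiplicative fold-change in
  their organ's samples (flower and fruit samples both carry the
  reproductive "flower/fruit" signal);
* multiplicative log-normal noise per sample;
* partial conservation: each orthogroup keeps its planted organ across
  species with a configurable probability, and ortholog pairs are dropped
  at a configurable loss rate;
* a two-species developmental stage series built from Gaussian-bump
  archetypes peaking at six flower-to-fruit cluster positions;
* planted co-expression modules (equicorrelated latent-factor construction)
  with one designated seed gene each, plus gene-family annotations carrying
  a planted seed-family association.

Everything is reproducible from a single seed; per-species streams are
derived deterministically so one species' output is stable under config
edits affecting another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cross_species import OrthologSet, build_orthogroups
from .expression_io import (
    FLOWER_FRUIT,
    AnnotationTable,
    ExpressionMatrix,
)
from .specificity import OrganSpecificSet
from .stage_clustering import DEFAULT_CONDITIONS

#: Planted class labels: four organ classes plus broadly expressed genes.
ORGAN_CLASSES: tuple[str, ...] = ("root", "stem", "leaf", FLOWER_FRUIT)
BROAD = "broad"

#: Condition index (within DEFAULT_CONDITIONS) at which each of the six
#: stage archetypes peaks: flower bud, open flower, young fruit, green
#: fruit, breaker red, mature fruit.
DEFAULT_ARCHETYPE_PEAKS: tuple[int, ...] = (3, 4, 5, 7, 9, 11)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic atlas.

    Defaults mirror the pipeline's reference scenario: two species of 2000
    genes, four organ classes sampled in triplicate, a 20-fold
    organ-specific signal over a log-normal baseline with log-sd 0.5 noise,
    10% of genes planted organ-specific (2.5% per class), 90% ortholog
    conservation.
    """

    seed: int = 0
    n_species: int = 2
    genes_per_species: int = 2000
    organs: tuple[str, ...] = ("root", "stem", "leaf", "flower", "fruit")
    replicates: int = 3
    specific_fraction_per_class: float = 0.025
    fold_change: float = 20.0
    fold_change_log_sd: float = 0.75
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.5
    conservation_rate: float = 0.9
    gene_loss_rate: float = 0.05
    # stage series
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    archetype_peaks: tuple[int, ...] = DEFAULT_ARCHETYPE_PEAKS
    genes_per_archetype: int = 40
    stage_noise_sd: float = 0.2
    stage_shift_b: int = 0
    stage_bump_width: float = 0.8
    stage_amplitude: float = 50.0
    # co-expression modules
    n_modules: int = 1
    module_size: int = 40
    module_rho: float = 0.9
    module_samples: int = 50
    module_background_genes: int = 2000
    family_size: int = 50
    n_families: int = 40

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise SimulationError("fold_change must exceed 1")
        n_classes = len(ORGAN_CLASSES)
        if self.specific_fraction_per_class * n_classes > 1:
            raise SimulationError("planted fractions exceed the gene count")
        if not 0 <= self.conservation_rate <= 1:
            raise SimulationError("conservation_rate must lie in [0, 1]")
        if not 0 <= self.gene_loss_rate <= 1:
            raise SimulationError("gene_loss_rate must lie in [0, 1]")
        if not 0 < self.module_rho < 1:
            raise SimulationError("module_rho must lie in (0, 1)")
        if self.module_size < 2:
            raise SimulationError("module_size must be >= 2")
        if len(self.archetype_peaks) > len(self.conditions):
            raise SimulationError("more archetypes than conditions")
        planted = self.n_modules * self.module_size
        if planted > self.module_background_genes:
            raise SimulationError("module genes exceed the module gene count")
        n_spec = int(round(
            self.specific_fraction_per_class * self.genes_per_species
        )) * n_classes
        if n_spec > self.genes_per_species:
            raise SimulationError("planted specific genes exceed gene count")


def species_names(config: SimulationConfig) -> list[str]:
    return [f"sp{chr(ord('A') + i)}" for i in range(config.n_species)]


def _species_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    # deterministic sub-stream per species, stable under unrelated edits
    return np.random.default_rng([config.seed, 7919, index])


@dataclass
class GroundTruth:
    """Planted classes and associations emitted alongside the matrices."""

    gene_class: pd.DataFrame  # species, gene_id, truth_class, truth_detail
    conserved_orthogroup: dict[str, bool] = field(default_factory=dict)
    planted_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def classes_of(self, species: str) -> pd.Series:
        sub = self.gene_class[self.gene_class["species"] == species]
        return pd.Series(sub["truth_class"].values, index=sub["gene_id"].values)

    def to_frame(self) -> pd.DataFrame:
        return self.gene_class.copy()


@dataclass
class SimulatedAtlas:
    expressions: dict[str, ExpressionMatrix]
    pair_tables: list[tuple[str, str, pd.DataFrame]]
    orthologs: OrthologSet
    truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        """Emit every TSV dialect consumed by the pipeline; returns a map of
        logical name -> path."""
        import os

        from .expression_io import write_expression

        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}
        for sp, expr in self.expressions.items():
            e = os.path.join(outdir, f"{sp}_expression.tsv")
            m = os.path.join(outdir, f"{sp}_samples.tsv")
            write_expression(expr, e, m)
            paths[f"expression:{sp}"] = e
            paths[f"metadata:{sp}"] = m
        manifest_rows = []
        for sa, sb, tab in self.pair_tables:
            p = os.path.join(outdir, f"orthologs_{sa}_{sb}.tsv")
            tab.to_csv(p, sep="\t", index=False)
            manifest_rows.append((os.path.basename(p), sa, sb))
            paths[f"orthologs:{sa}-{sb}"] = p
        manifest = os.path.join(outdir, "ortholog_manifest.tsv")
        pd.DataFrame(
            manifest_rows, columns=["file_path", "species_a", "species_b"]
        ).to_csv(manifest, sep="\t", index=False)
        paths["ortholog_manifest"] = manifest
        truth_path = os.path.join(outdir, "ground_truth.tsv")
        self.truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        paths["ground_truth"] = truth_path
        return paths


def _assign_classes(
    rng: np.random.Generator, n_genes: int, per_class: int
) -> np.ndarray:
    classes = np.array([BROAD] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    pos = 0
    for organ in ORGAN_CLASSES:
        classes[order[pos : pos + per_class]] = organ
        pos += per_class
    return classes


def simulate_atlas(config: SimulationConfig) -> SimulatedAtlas:
    """Generate per-species expression atlases with planted organ-specific
    genes, partially conserved across species through shared orthogroups."""
    n = config.genes_per_species
    per_class = int(round(config.specific_fraction_per_class * n))
    if per_class * len(ORGAN_CLASSES) > n:
        raise SimulationError("planted specific genes exceed the gene count")
    names = species_names(config)
    rng = np.random.default_rng([config.seed, 104729])
    baseline_log = rng.normal(
        config.baseline_log_mean, config.baseline_log_sd, size=n
    )
    classes_a = _assign_classes(rng, n, per_class)

    # per-species class maps: conserved orthogroups inherit species A's
    # class; a non-conserved organ-specific orthogroup switches to a
    # different organ class (broad genes stay broad, so each species keeps
    # the configured planted fraction)
    class_by_species: dict[str, np.ndarray] = {names[0]: classes_a}
    specific = classes_a != BROAD
    conserved = np.ones(n, dtype=bool)
    for si, sp in enumerate(names[1:], start=1):
        srng = _species_rng(config, si)
        keep = ~specific | (srng.random(n) < config.conservation_rate)
        conserved &= keep
        cls = classes_a.copy()
        pool = np.array(ORGAN_CLASSES, dtype=object)
        for i in np.where(~keep)[0]:
            alternatives = pool[pool != classes_a[i]]
            cls[i] = srng.choice(alternatives)
        class_by_species[sp] = cls

    organ_class_of_sample = {
        o: (FLOWER_FRUIT if o in ("flower", "fruit") else o)
        for o in config.organs
    }
    # per-orthogroup signal strength, shared across species: specificity is
    # graded, so strict top-k% cuts select the same extreme orthogroups in
    # every species carrying the signal
    log_fc = np.log(config.fold_change) + rng.normal(
        0.0, config.fold_change_log_sd, size=n
    )

    expressions: dict[str, ExpressionMatrix] = {}
    truth_rows: list[tuple[str, str, str, str]] = []
    for si, sp in enumerate(names):
        srng = _species_rng(config, 1000 + si)
        gene_ids = [f"{sp}_g{i:05d}" for i in range(n)]
        cols: dict[str, np.ndarray] = {}
        meta_rows = []
        cls = class_by_species[sp]
        for organ in config.organs:
            oc = organ_class_of_sample[organ]
            boost = np.where(cls == oc, log_fc, 0.0)
            for rep in range(1, config.replicates + 1):
                noise = srng.normal(0.0, config.noise_log_sd, size=n)
                cols[f"{sp}_{organ}_r{rep}"] = np.exp(
                    baseline_log + boost + noise
                )
                meta_rows.append((f"{sp}_{organ}_r{rep}", organ, "", rep))
        values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "organ", "stage", "replicate"]
        ).set_index("sample_id")
        expressions[sp] = ExpressionMatrix(values, meta)
        for i, g in enumerate(gene_ids):
            truth_rows.append((sp, g, str(cls[i]), f"og{i:05d}"))

    # ortholog pair files: 1-1 pairs per orthogroup, thinned by the loss rate
    pair_tables: list[tuple[str, str, pd.DataFrame]] = []
    prng = np.random.default_rng([config.seed, 15485863])
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            sa, sb = names[ai], names[bi]
            kept = prng.random(n) >= config.gene_loss_rate
            tab = pd.DataFrame(
                {
                    f"gene_{sa}": [f"{sa}_g{i:05d}" for i in np.where(kept)[0]],
                    f"gene_{sb}": [f"{sb}_g{i:05d}" for i in np.where(kept)[0]],
                }
            )
            pair_tables.append((sa, sb, tab))
    orthologs = build_orthogroups(pair_tables)
    truth = GroundTruth(
        gene_class=pd.DataFrame(
            truth_rows,
            columns=["species", "gene_id", "truth_class", "truth_detail"],
        ),
        conserved_orthogroup={f"og{i:05d}": bool(conserved[i]) for i in range(n)},
    )
    return SimulatedAtlas(expressions, pair_tables, orthologs, truth)


# ---------------------------------------------------------------------------
# Stage series
# ---------------------------------------------------------------------------

def _archetype_profiles(config: SimulationConfig) -> np.ndarray:
    """One Gaussian-bump TPM profile per archetype over the condition order."""
    pos = np.arange(len(config.conditions), dtype=float)
    profiles = []
    for peak in config.archetype_peaks:
        bump = np.exp(
            -0.5 * ((pos - peak) / config.stage_bump_width) ** 2
        )
        profiles.append(1.0 + config.stage_amplitude * bump)
    return np.vstack(profiles)


@dataclass
class SimulatedStageSeries:
    expressions: dict[str, ExpressionMatrix]
    gene_sets: dict[str, OrganSpecificSet]
    orthologs: OrthologSet
    truth: GroundTruth  # truth_class = archetype id ("archetype_1"...)


def simulate_stage_series(config: SimulationConfig) -> SimulatedStageSeries:
    """Two-species stage series from Gaussian-bump archetypes.

    Each orthogroup is assigned one of k archetypes. Species A genes follow
    their archetype; with ``stage_shift_b`` = s, species B genes follow the
    archetype s cluster positions later (clamped at the last), creating the
    off-diagonal structure a developmental delay would produce. Noise is
    multiplicative log-normal with sd ``stage_noise_sd``.
    """
    k = len(config.archetype_peaks)
    if k < 2:
        raise SimulationError("need at least two archetypes")
    profiles = _archetype_profiles(config)
    n = k * config.genes_per_archetype
    arch = np.repeat(np.arange(k), config.genes_per_archetype)
    names = species_names(replace(config, n_species=2))
    expressions: dict[str, ExpressionMatrix] = {}
    gene_sets: dict[str, OrganSpecificSet] = {}
    truth_rows = []
    for si, sp in enumerate(names):
        srng = _species_rng(config, 2000 + si)
        shift = config.stage_shift_b if si == 1 else 0
        eff = np.minimum(arch + shift, k - 1)
        gene_ids = [f"{sp}_s{i:05d}" for i in range(n)]
        base = profiles[eff]  # n × conditions
        noise = srng.normal(0.0, config.stage_noise_sd, size=base.shape)
        tpm = base * np.exp(noise)
        cols = {}
        meta_rows = []
        for ci, cond in enumerate(config.conditions):
            sid = f"{sp}_{cond}_r1"
            cols[sid] = tpm[:, ci]
            organ = cond if cond in ("root", "stem", "leaf") else (
                "flower" if "flower" in cond else "fruit"
            )
            meta_rows.append((sid, organ, "" if cond in ("root", "stem", "leaf") else cond, 1))
        values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "organ", "stage", "replicate"]
        ).set_index("sample_id")
        expressions[sp] = ExpressionMatrix(values, meta)
        gene_sets[sp] = OrganSpecificSet(
            sp, FLOWER_FRUIT, 0.10, frozenset(gene_ids)
        )
        for i, g in enumerate(gene_ids):
            truth_rows.append(
                (sp, g, f"archetype_{int(eff[i]) + 1}", f"sog{i:05d}")
            )
    pair_tab = pd.DataFrame(
        {
            f"gene_{names[0]}": [f"{names[0]}_s{i:05d}" for i in range(n)],
            f"gene_{names[1]}": [f"{names[1]}_s{i:05d}" for i in range(n)],
        }
    )
    orthologs = build_orthogroups([(names[0], names[1], pair_tab)])
    truth = GroundTruth(
        gene_class=pd.DataFrame(
            truth_rows,
            columns=["species", "gene_id", "truth_class", "truth_detail"],
        )
    )
    return SimulatedStageSeries(expressions, gene_sets, orthologs, truth)


# ---------------------------------------------------------------------------
# Co-expression modules
# ---------------------------------------------------------------------------

@dataclass
class SimulatedModules:
    expression: ExpressionMatrix
    seeds: list[str]
    families: AnnotationTable
    truth: GroundTruth  # truth_class = "module_i" or "background"


def simulate_modules(config: SimulationConfig) -> SimulatedModules:
    """Planted co-expression modules in an otherwise independent background.

    Module genes share a latent factor: on the log2(TPM+1) scale each module
    gene is sqrt(rho) * latent + sqrt(1-rho) * independent noise, so the
    expected intra-module Pearson correlation is rho. The first gene of each
    module is its designated seed. Gene families are annotated such that one
    family per module contains the whole module (padded with random
    background genes up to ``family_size``) — the planted enrichment — and
    the remaining families are random background draws.
    """
    rng = np.random.default_rng([config.seed, 32452843])
    n = config.module_background_genes
    m = config.module_samples
    n_mod_genes = config.n_modules * config.module_size
    gene_ids = [f"tom_g{i:05d}" for i in range(n)]
    Z = rng.normal(size=(n, m))  # independent component, log2 scale
    log2 = 5.0 + 2.0 * Z
    truth_cls = np.array(["background"] * n, dtype=object)
    seeds: list[str] = []
    for mod in range(config.n_modules):
        latent = rng.normal(size=m)
        lo = mod * config.module_size
        hi = lo + config.module_size
        mix = np.sqrt(config.module_rho) * latent + np.sqrt(
            1 - config.module_rho
        ) * Z[lo:hi]
        log2[lo:hi] = 5.0 + 2.0 * mix
        truth_cls[lo:hi] = f"module_{mod + 1}"
        seeds.append(gene_ids[lo])
    tpm = np.clip(np.exp2(log2) - 1.0, 0.0, None)
    organs_cycle = ["root", "stem", "leaf", "flower", "fruit"]
    cols, meta_rows = {}, []
    for j in range(m):
        organ = organs_cycle[j % len(organs_cycle)]
        sid = f"tom_s{j:03d}"
        cols[sid] = tpm[:, j]
        meta_rows.append((sid, organ, "", j // len(organs_cycle) + 1))
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "organ", "stage", "replicate"]
    ).set_index("sample_id")
    expression = ExpressionMatrix(values, meta)

    # annotations: one planted family per module + random families
    gene_to_terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    planted_terms: dict[str, frozenset[str]] = {}
    background_pool = np.array(gene_ids[n_mod_genes:])
    for mod in range(config.n_modules):
        term = f"FAM_planted_{mod + 1}"
        labels[term] = f"planted family of module {mod + 1}"
        members = set(
            gene_ids[mod * config.module_size : (mod + 1) * config.module_size]
        )
        pad = config.family_size - len(members)
        if pad > 0:
            members |= set(
                rng.choice(background_pool, size=pad, replace=False)
            )
        planted_terms[term] = frozenset(members)
        for g in members:
            gene_to_terms.setdefault(g, set()).add(term)
    for f in range(config.n_families):
        term = f"FAM_{f + 1:03d}"
        labels[term] = f"background family {f + 1}"
        members = rng.choice(background_pool, size=config.family_size, replace=False)
        for g in members:
            gene_to_terms.setdefault(g, set()).add(term)
    families = AnnotationTable(
        {g: frozenset(ts) for g, ts in gene_to_terms.items()}, labels
    )
    truth = GroundTruth(
        gene_class=pd.DataFrame(
            {
                "species": "tom",
                "gene_id": gene_ids,
                "truth_class": truth_cls,
                "truth_detail": ["seed" if g in seeds else "" for g in gene_ids],
            }
        ),
        planted_terms=planted_terms,
    )
    return SimulatedModules(expression, seeds, families, truth)


def simulate_annotations(
    rng: np.random.Generator,
    genes: list[str],
    n_terms: int = 50,
    term_size: int = 40,
) -> AnnotationTable:
    """Random flat annotations with no planted structure (null model)."""
    gene_to_terms: dict[str, set[str]] = {}
    arr = np.array(genes)
    for t in range(n_terms):
        term = f"T{t + 1:03d}"
        for g in rng.choice(arr, size=min(term_size, len(arr)), replace=False):
            gene_to_terms.setdefault(g, set()).add(term)
    return AnnotationTable(
        {g: frozenset(ts) for g, ts in gene_to_terms.items()}
    )
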