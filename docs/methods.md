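# Methods

This note documents the statistical procedures implemented in `solatlas`,
the defaults they run with, what the synthetic generator does and does not
emulate, and the design choices made where the problem was genuinely open.

## Organ profiles and the expressed-gene filter

Input is a genes × samples TPM matrix per species with per-sample organ,
stage and replicate metadata (`counts_to_tpm` converts raw counts given
gene lengths in kb; each sample column then sums to 10⁶). Samples are
collapsed to per-organ means with every sample weighted equally — a flat
mean over replicates and stages. The alternative (mean of per-stage means,
which re-weights unbalanced stage designs such as many fruit stages versus
two flower stages) is available as `stage_weighted=True`; the flat mean is
the default because it is the simplest defensible reading and the two
coincide for balanced designs. Flower and fruit samples are merged into a
single reproductive "flower/fruit" organ before averaging (both are
reproductive tissue and their specific genes overlap heavily), giving the
canonical four-organ scheme root, stem, leaf, flower/fruit. The organ
vocabulary is configurable for other designs.

A gene is *expressed* when its maximum organ mean is **strictly** greater
than 2 TPM; boundary genes at exactly 2 are excluded. All downstream
backgrounds (enrichment universes, SPM pools) are the expressed genes of a
species — the population the organ-specific sets were drawn from.

## SPM and organ-specific calls

SPM(g, o) = mean(g, o) / Σ_o′ mean(g, o′). Rows are stochastic (sum to 1);
an all-zero gene has no defined SPM and must be removed by the expressed
filter. Argmax ties break to the first organ in canonical order —
deterministic and documented.

Thresholds are quantiles of the **pooled per-gene maximum SPM** within one
species: at fraction f the cut is the nearest-rank (1−f) quantile, a gene
is organ-specific iff max-SPM ≥ cut, and it is assigned to its argmax
organ. Pooling maxima (rather than one pooled distribution of all
genes × organs values) counts each gene once, gives a single threshold per
species and fraction, and makes the per-organ sets disjoint by
construction. Ties exactly at the cut are all included, so a set may
slightly exceed f·n genes. Stricter sets are nested inside looser ones.

## Orthogroups and cross-species similarity

Syntenic ortholog pairs (two-column TSV per species pair, listed in a
manifest) form an undirected graph over gene ids; orthogroups are its
connected components, identified by their lexicographically smallest member
id. Connected components are the only reading that makes set comparison
well defined under many-to-many pairing.

An organ-specific set is projected to the ids of orthogroups containing at
least one of its genes **and** at least one gene of the partner species
(the comparable universe; without the restriction, lineage-specific genes
deflate similarity for reasons unrelated to expression — the unrestricted
variant is available via `restrict_universe=False`). Genes in no
orthogroup are dropped and counted. Similarity is the Jaccard coefficient
on orthogroup-id sets, defined as 0 for two empty sets (with a warning).

Same-organ versus cross-organ JSC distributions are compared by the
two-sided Mann–Whitney/Wilcoxon rank-sum test: exact when both groups hold
at most 20 records, otherwise the normal approximation with mid-rank tie
correction. The statistic is rank-based and invariant to monotone
transforms of JSC. The CLI pools thresholds per organ (and reports a
fully pooled row) because a two-species run yields a single same-organ
record per organ and threshold.

## Stage clustering

Both species' flower/fruit-specific genes (top-10% calls) are profiled
over a shared ordered condition axis — by default root, stem, leaf, flower
bud, open flower, then young-fruit, green-fruit, breaker-red and
mature-fruit periods (two each; 13 conditions). Replicates are averaged
per condition, each gene is z-scored across conditions (constant profiles
are dropped — they have no shape), and the two species are stacked into one
matrix.

Clustering is agglomerative with Ward linkage on Euclidean distance, cut to
exactly k = 6 clusters. This is a deterministic, dependency-free procedure
with no random initialisation: identical input gives identical output.
Clusters are relabelled I..k by the condition at which their centroid
peaks, so labels are comparable across runs and species. A gene's
membership is the Pearson correlation of its profile with its cluster
centroid, floored at 0 — a documented stand-in for fuzzy-membership scores,
chosen because it needs no extra fitting.

Cross-species correspondence: entry (i, j) of the cluster-JSC matrix is the
orthogroup Jaccard between species-A genes of cluster i and species-B genes
of cluster j. Aligned series put mass on the diagonal; a one-stage
developmental delay in one species moves it to the superdiagonal.

## Co-expression networks

PCC is computed over all samples of the species on log2(TPM+1) (the
default variance stabilisation; `transform="none"` is available). Constant
genes get correlation 0 everywhere and are flagged.

Mutual rank: each gene ranks its partners by descending PCC with **ordinal**
ranks, ties broken by ascending partner gene id; MR(a,b) =
sqrt(rank_a(b)·rank_b(a)) ≥ 1. Ordinal ranks with an id tie-break keep MR
reproducible under any sort order; average-rank conventions used by some
co-expression databases can differ on tied inputs, and that divergence is
accepted.

Edge retention: PCC ≥ cutoff **and** (the pair is within either endpoint's
top-3 smallest-MR partners **or** MR ≤ 30). The PCC gate is conjunctive —
a strong mutual rank cannot rescue a weak correlation; a union variant is
exposed as `gate="union"`. The default cutoff is the 95th percentile of
positive off-diagonal PCC values, recomputed per dataset (a fixed numeric
cutoff is a dataset-specific realisation of the same rule and can be passed
directly). Retained-edge counts are monotone in all three knobs.

Seed neighborhoods take every gene with PCC ≥ the global positive-PCC 95th
percentile to a seed; the union of non-seed partners across seeds is tested
for gene-family enrichment (hypergeometric upper tail per family with ≥ 1
partner, BH across families).

## Enrichment

`hypergeom_upper_tail(k, K, n, N)` is P(X ≥ k) under the hypergeometric
distribution, evaluated via the stable survival function. BH adjustment is
the step-up procedure with monotonicity enforcement, returned in input
order and capped at 1. Families of tests are one gene set × one annotation
source (pathways, TF families and gene families adjusted separately);
significance is padj < 0.05, with the raw p < 0.05 gate also emitted as a
column so either convention can be read off the output.

## Synthetic data: what it emulates and what it does not

`simulate_atlas` draws one log-normal baseline per orthogroup
(log-mean 3.0, log-sd 1.0 — a right-skewed bulk profile with median ≈ 20
TPM, so nearly all genes clear the TPM > 2 filter) shared by orthologous
genes. A planted organ-specific gene multiplies its organ's samples by a
per-orthogroup fold-change, log-normal with geometric mean 20 and log-sd
0.75 and shared across species: real specificity is graded, and the shared
grading is what makes strict top-k% cuts select the same extreme
orthogroups in every species. Per-sample noise is multiplicative
log-normal with log-sd 0.5. Defaults: two species × 2000 genes, four organ
classes sampled in triplicate (flower and fruit samples both carry the
flower/fruit signal), 2.5% of genes planted per class (10% total, matching
the top-10% call fraction), ortholog conservation 0.9 (a non-conserved
specific orthogroup switches to a different organ in the partner species;
broad genes stay broad), pair loss rate 0.05.

`simulate_stage_series` assigns each orthogroup one of six Gaussian-bump
archetypes peaking at the six cluster positions of the condition axis; the
optional one-stage shift advances each species-B gene to the **next
archetype** (clamped at the last). The shift is in archetype space rather
than a literal translation of the bump because the combined two-species
clustering is cut at exactly k: translating bumps by one condition creates
up to 2k interleaved, equidistant profiles whose forced merges are
arbitrary, destroying the planted correspondence that the shift exists to
create; advancing archetypes keeps exactly k planted profiles and yields
the intended superdiagonal structure.

`simulate_modules` builds module genes as sqrt(ρ)·latent + sqrt(1−ρ)·noise
on the log2(TPM+1) scale (target intra-module correlation ρ = 0.9, module
size 40, 50 samples, 2000 genes), with one designated seed gene per module
and one planted gene family containing the module padded to 50 members;
decoy families are random draws.

Deterministic throughout: one root seed, with per-species sub-streams
derived from fixed offsets so one species' output is stable under edits
affecting another.

**Not emulated:** count-level (negative-binomial) noise — the pipeline
consumes TPM, so noise is modelled on the TPM scale; genome-scale gene
counts (sizes are config-scaled); many-to-many orthology in the generator
(the builder supports it; the generator emits 1–1 pairs with losses);
library-size or batch effects; correlated noise between organs. Passing
tests therefore show that the statistics recover the structure they are
designed for under a faithful-but-idealised noise model, not that any
particular biological dataset will behave as cleanly.

## Problem sizes and numerical choices

The reference scenario (2000 genes × 2 species, 15 samples each; 480
stage profiles; 2000-gene module matrix; 200 null gene sets over 50 terms)
runs the whole suite and the acceptance script in a few seconds while
keeping every estimate far from its decision boundary; it is the scale at
which the generator's recovery guarantees were designed. Quantiles use the
nearest-rank convention; argmax and rank ties break deterministically as
described; z-scores use population (ddof = 0) standard deviations; Jaccard
of empty sets is 0; all-zero TPM columns are zeroed with a warning rather
than erroring.

## Known limitations

- The top-k% quantile is taken over each gene's maximum SPM; conventions
  that pool all genes × organ values would shift thresholds slightly for
  skewed organ distributions.
- Whether quantile-tied genes are included is a convention
  (nearest-rank-inclusive here); set sizes can exceed k% under heavy ties.
- JSC is computed on orthogroups, not raw pairs; a pair-based variant would
  differ under many-to-many orthology and is not built.
- Agglomerative Ward clustering is one of several reasonable stage
  clusterers; exact replication of fuzzy-clustering packages' output is not
  promised, and the membership score is a stand-in, not their membership
  function.
- The rank-sum exact/asymptotic switch at group size 20 is a convention;
  near the switch, p-values differ at the third decimal under ties.
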