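# solatlas

Comparative multi-organ transcriptomics for plant atlases: which genes are
specific to roots, stems, leaves, or the reproductive flower/fruit system,
and how conserved is that organ-specific expression between related species?

`solatlas` implements, as a tested reusable pipeline:

- **Organ-specificity scoring.** After collapsing a genes × samples TPM
  matrix to per-organ means (flower and fruit merged into one reproductive
  organ) and filtering to expressed genes (TPM > 2 in at least one organ),
  each gene gets a specificity measure
  SPM(g, o) = mean(g, o) / Σ_o' mean(g, o'), a vector on the simplex where 1
  means exclusive expression in one organ. Organ-specific genes are called
  at the top 2%, 5%, 10% and 20% of the pooled per-gene maximum SPM and
  assigned to their argmax organ.
- **Cross-species conservation.** Syntenic ortholog pair files are merged
  into orthogroups (connected components of the pair graph); organ-specific
  sets are projected onto orthogroup ids and compared between species by
  the Jaccard similarity coefficient JSC = |A∩B| / |A∪B|, with same-organ
  versus cross-organ JSC distributions tested by the Wilcoxon rank-sum test.
- **Developmental-stage clustering.** The two species' flower/fruit-specific
  genes are z-scored over a shared ordered condition axis (vegetative organs
  plus a ten-stage flower-to-mature-fruit series), stacked, and cut into
  k = 6 clusters by Ward-linkage hierarchical clustering; cross-species
  cluster correspondence is a k × k orthogroup-level JSC matrix.
- **Mutual-rank co-expression networks.** From an all-pairs Pearson
  correlation matrix (log2(TPM+1)), MR(a, b) = sqrt(rank_a(b) · rank_b(a));
  an edge is kept when PCC clears the 95th percentile of positive
  correlations and the pair is in either endpoint's MR top-3 or has
  MR ≤ 30. Seed-gene (e.g. YABBY) neighborhoods are extracted at the global
  top-PCC threshold and their gene families tested for hypergeometric
  enrichment with Benjamini–Hochberg control.
- **A ground-truthed synthetic generator** that emulates the statistical
  structure of such an atlas (shared log-normal baselines per orthogroup,
  multiplicative organ signals, partial ortholog conservation, stage
  archetypes, planted co-expression modules), so every stage is testable
  end to end without sequencing data.

## Worked example

```python
from solatlas import (
    SimulationConfig, simulate_atlas, collapse_to_organs, filter_expressed,
    compute_spm, call_specific, organ_share, pairwise_similarity,
    compare_same_vs_cross,
)

atlas = simulate_atlas(SimulationConfig(seed=42))
sets = {}
for species, expr in atlas.expressions.items():
    profile = filter_expressed(collapse_to_organs(expr))   # TPM > 2
    table = compute_spm(profile)
    sets[species] = call_specific(table, species)          # top 2/5/10/20%

shares = organ_share([s for s in sets["spA"] if s.fraction == 0.02])
print("top-2% organ shares:", {o: round(v, 3) for o, v in shares.items()})

records = pairwise_similarity(sets["spA"], sets["spB"], atlas.orthologs)
same = [r.jsc for r in records if r.fraction == 0.02 and r.organ_a == r.organ_b]
print("top-2% same-organ JSC:", [round(j, 3) for j in same])
(test,) = compare_same_vs_cross(records, per_organ=False)
print(f"same vs cross rank-sum p = {test.pvalue:.2e}")
```

prints

```
top-2% organ shares: {'root': 0.25, 'stem': 0.25, 'leaf': 0.225, 'flower/fruit': 0.275}
top-2% same-organ JSC: [0.7, 0.583, 0.222, 0.583]
same vs cross rank-sum p = 1.41e-09
```

The shares say how the strictest organ-specific calls distribute over the
four organs (the generator plants them almost uniformly); the same-organ JSC
values (root, stem, leaf, flower/fruit) are far above the cross-organ ones,
and the rank-sum test confirms that same-organ specificity is conserved
between the two synthetic species far beyond chance.

The same pipeline is available from the shell:

```bash
solatlas --seed 42 --outdir demo all      # simulate → specificity → jsc →
                                          # cluster → coexpress → enrich
```

Each stage writes TSV artifacts plus a `run_manifest.json` with parameters
and SHA-256 checksums; reruns are byte-identical.

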