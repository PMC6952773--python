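# triomix

Pathway-level integration of transcriptomic, proteomic and metabolomic
profiles, built for studies that ask whether a perturbation leaves a
*persistent, cross-layer* signature — for example gestational hypoxia acting
on the developing heart across fetal and adult, male and female animals.
Any single omics layer at small replicate numbers is noisy; features that
barely miss significance in one layer can still carry real signal when the
transcript, protein and metabolite evidence all point the same way.
`triomix` operationalizes that idea as a tested, reusable pipeline, and
ships a synthetic-data generator with planted cross-layer modules so every
stage can be validated without any external download.

## What the pipeline computes

1. **Preprocessing** — each quantitative matrix is normalized assuming equal
   total ion counts (every sample column rescaled to the mean column total);
   proteins identified by a single unique peptide ("singlets") are removed;
   per-feature differential statistics for a hypoxia-vs-normoxia contrast
   use a Welch t-test on log2 intensities, with a feature called significant
   when the linear fold change exceeds 15% and p < 0.05. PCA of samples and
   silhouette-guided K-means summarize sample-level structure.
2. **Proteogenomics** — a six-frame in-silico translation of assembled
   transcripts enumerates all possible encoded peptides (maximal stop-free
   stretches); reference proteins with no exact shared substring of at least
   30 aa with any ORF are removed, yielding a transcript-evidence-filtered
   custom proteome database.
3. **Pathway integration** — every layer is mapped to pathways through
   genes: metabolites via pathway membership, proteins via their gene ids,
   transcripts via gene clusters (groups of sequence/function-similar
   genes). For each pathway and layer a competitive permutation test asks
   whether the pathway's members have a larger mean |t| than random member
   sets of the same size. Per-layer p-values are combined with Fisher's
   method,

       X² = −2 Σᵢ ln pᵢ   ~   χ²(2k),

   treating the k testable layers as independent observations of the same
   biological system. Because overlapping pathways reuse the same data
   points, pathways are then re-ranked under an assignment cap: each
   metabolite/protein/transcript may support at most M pathways, every
   retained pathway must keep at least `min_members` entities, and the
   retained set maximizes Σ −log10(combined p) (solved exactly on small
   instances via max-flow feasibility, greedily at scale).
4. **Cluster extraction and enrichment** — standardized cross-layer feature
   profiles are embedded with t-SNE (perplexity 20, first 50 PCA
   components, early exaggeration 4, 15 seeded repeats); density-based
   labels are combined across runs into a consensus, clusters separating
   from the main data stream are extracted and directed by their mean
   fetal-minus-adult profile (group 1 = up in fetal, group 2 = down), and
   query sets are tested for annotation enrichment with a one-sided
   hypergeometric test and Benjamini–Hochberg FDR.
5. **Biomarker panels** — all combinations of 1–6 features from a top-K
   univariate pool are tested with MANOVA (Wilks' Λ, Rao's F, exact for two
   groups); panels beating every member's singleton p-value are flagged
   synergistic.

## Worked example

Simulate the default study design (3 groups × 2 conditions × 5 replicates,
a 12-gene/4-metabolite module shifted by log2 effect 1.0 under hypoxia in
all three layers, noise sd 0.25, plus a decoy pathway sharing 50% of the
module), then integrate:

```python
import numpy as np
from triomix import (SimulationConfig, simulate_dataset, tic_normalize,
                     filter_singletons, differential_test, map_layers,
                     score_pathways, dp_rank, rank_report, enrich)
from triomix.integration import integrated_significant_features

dataset = simulate_dataset(SimulationConfig(seed=1))
layers = {tag: tic_normalize(layer) for tag, layer in dataset.layers().items()}
layers["protein"] = filter_singletons(layers["protein"])
diff = {tag: differential_test(layer, dataset.metadata) for tag, layer in layers.items()}
membership = map_layers(layers, dataset.pathway_db, dataset.gene_cluster_map)
table = score_pathways({t: d["t"] for t, d in diff.items()}, membership,
                       n_permutations=10_000, rng=np.random.default_rng(1))
scores = {pw: -np.log10(p) for pw, p in table["combined_p"].dropna().items()}
solution = dp_rank(scores, membership.entities_by_pathway(), cap=2)
print(rank_report(solution, table)[["combined_p", "fdr", "n_entities_retained", "rank"]].head(4))
```

prints

```
                combined_p           fdr  n_entities_retained  rank
pathway
pw_planted_1  4.102532e-10  4.923038e-09                   28     1
pw_decoy_1    3.744798e-07  2.246879e-06                   23     2
pw_null_10    5.292482e-01  9.854600e-01                   23     3
pw_null_03    5.753329e-01  9.854600e-01                   24     4
```

The planted pathway ranks first: its permutation p-value hits the floor in
all three layers, so the Fisher combination across six degrees of freedom
is far below any null pathway. The decoy ranks second — half its members
are planted genes — but with assignment cap 1 those shared entities are
claimed by the stronger planted pathway and the decoy is demoted. Enriching
the features significant in ≥2 layers against the annotation terms:

```
          term  k  K count_in_set            p          fdr
term_planted_1 12 12        12/12 3.100404e-18 4.960646e-17
  term_null_08  1 11         1/11 5.434829e-01 1.000000e+00
```

All 12 planted genes are recovered (`count_in_set` = 12/12) and the planted
term's FDR is ~17 orders of magnitude below the best null term.

The same analysis is available from the shell:

```bash
triomix simulate --out fixtures --seed 1
triomix run-all --out run1 --seed 1
triomix build-proteome-db --transcripts fixtures/transcripts.fasta \
    --reference fixtures/reference_proteome.fasta --out-fasta custom.fasta
```

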