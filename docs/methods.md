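# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Study design emulated by the generator

The pipeline targets a three-layer design: transcript, protein and
metabolite abundances measured in the same tissues over six sample groups —
fetal, adult-male and adult-female subjects whose mothers experienced
either normoxia or hypoxia during gestation — with n = 5 replicates per
(group, condition) cell (30 samples per layer).

The generator (`triomix.simulate`) draws per-feature baselines uniformly on
log2 ∈ [6, 12] and adds i.i.d. Gaussian noise on the log2 scale
(`noise_sd`, default 0.25), i.e. multiplicative log-normal noise on the
intensity scale for all three layers. Transcript counts are rounded
log-normal intensities rather than negative-binomial counts: one noise
engine suffices because the pipeline consumes normalized intensities, never
raw reads. A planted module (default: 12 genes + 4 metabolites) receives a
constant-sign log2 shift (`log2_effect`, default 1.0 per layer) in every
hypoxia sample of every group — the "persistent change" the integration is
designed to detect — plus an optional developmental offset
(`fetal_log2_shift`, default +1.0) that gives embedding stages an
up-in-fetal direction to recover. Null features carry zero effect.

Alongside the matrices the generator emits: a pathway set containing the
planted pathway, a designated decoy sharing 50% of the planted genes (it
exists to make assignment-capped deduplication meaningful), and null
pathways of ~10 genes + 2 metabolites; annotation terms including one
covering the planted module; a gene → gene-cluster map in which some null
genes share clusters (exercising transcript-to-cluster mapping); and
transcript/reference-proteome FASTA files in which a known 70% of reference
proteins are exactly encoded (over an 80-aa window) by some transcript.

All randomness flows through a single seeded PCG64 generator; identical
configurations reproduce byte-identical datasets. Replicate-level variance
structure is a package parameter, not a claim about any particular study:
real data have correlated features, batch effects, heteroskedastic and
missing values, none of which are simulated. Passing the planted-recovery
checks therefore demonstrates correctness of the computations and
detectability under the stated conditions — not performance on real tissue.

## Preprocessing

* **TIC normalization** rescales each sample column to the mean of the
  original column totals, preserving within-sample feature proportions.
  Columns with non-positive totals are an error naming the sample.
* **Singlet filtering** drops proteins with unique-peptide count < 2; such
  identifications are too unreliable to quantify.
* **Differential statistics** use a Welch two-sample t-test on log2
  intensities. The test is deliberately the conservative default: with
  n = 5 per cell, equal-variance assumptions are not worth defending. The
  significance rule is |ratio − 1| > 0.15 (linear scale, both directions)
  AND p < 0.05; both thresholds are parameters. Ratios are means of linear
  intensities (numerator condition over denominator).
* **Zeros** are replaced by half the smallest positive value in the layer
  before logs — a floor, not an imputation; configurable by preprocessing
  the matrix beforehand.
* **PCA** operates on column-centered log2 matrices with samples as
  observations (full SVD solver, deterministic). **Silhouette-guided
  K-means** scans k = 2..10 with 25 restarts from a fixed base seed and
  picks the k maximizing mean silhouette, ties to the smallest k.

## Proteogenomics

ORFs are maximal stop-free stretches in each of the six reading frames —
no initiator methionine is required, since the goal is to enumerate *all
possible* encoded stretches, and peptide evidence does not begin at starts.
Codons containing N translate to X. `min_orf_len` defaults to 20 aa
(shorter fragments are below the scale of peptide evidence).

"Transcript-level evidence" for a reference protein is operationalized as
an exact ungapped shared amino-acid substring of ≥ `min_match_len` (default
30 aa) with some ORF — deterministic, aligner-free, and checkable by brute
force. Matching is seeded on shared 30-mers and extended greedily both
ways; the longest extension is reported as the supporting match. Raising
`min_match_len` can only shrink the retained set (asserted by test).

## Pathway-level integration

* **Mapping.** Metabolites map to pathways by metabolite membership;
  proteins by gene membership; transcripts map through gene clusters — a
  transcript joins a pathway when any gene of its cluster is a member.
  Unmapped features are a reported outcome, not an error. Entities are
  layer-tagged (`protein:g0001` ≠ `transcript:g0001`): each omics
  measurement is an independent data point for the assignment cap.
* **Per-layer pathway p-value.** A competitive permutation test: the
  pathway score is the mean |t| of its mapped members; p is the probability
  that a uniformly random member set of equal size scores at least as high.
  When C(n, k) ≤ 50 000 the tail is enumerated exactly (p ≥ 1/C(n, k),
  since the observed set counts itself); otherwise B = `n_permutations`
  (default 10 000) random sets are drawn and p = (1 + #{≥ obs})/(B + 1) —
  the +1 keeps p in [1/(B+1), 1] and avoids log(0) downstream. Layers
  contributing fewer than `min_members` (default 3) mapped features are
  omitted from that pathway's combination — the degrees of freedom shrink —
  rather than imputing p = 1, which would punish pathways for missing
  coverage.
* **Fisher combination.** X² = −2 Σ ln pᵢ against χ² with 2k degrees of
  freedom over the k testable layers. For a single layer this is the
  identity (χ²₂ survival = exp(−X²/2)).
* **Assignment-capped ranking.** Overlapping pathways reuse the same data
  points; to remove repetitive use, each entity may be assigned to at most
  `cap` (default 2) retained pathways and each retained pathway must keep
  at least `min_members` entities, while maximizing Σ −log10(combined p)
  over retained pathways. Instances with ≤ 16 candidate pathways are solved
  exactly: subsets are visited in decreasing objective order and the first
  feasible one is optimal, because feasibility (checked as a max-flow with
  per-entity capacity `cap` and per-pathway demand `min_members`) is closed
  under taking subsets. Larger instances use a documented greedy — process
  pathways by decreasing score, claim remaining entity capacity, drop
  pathways left with fewer than `min_members` available entities. The
  output records which regime ran. Whether the original analysis capped
  assignments at 1 or more was never quantified; both the cap and the
  objective are this package's interpretation, exposed as parameters.
* **Final ranking.** Pathways sort by combined p ascending; *exact* ties —
  which occur when overlapping pathways all hit the permutation floor — are
  broken by the number of entities each pathway kept after capping (more
  first: the pathway explaining more unclaimed data outranks), then by id.
  This entity-count tie-break is what demotes the 50%-overlap decoy below
  the planted pathway whenever cap = 1. BH FDR is computed over testable
  pathways.

## Cluster extraction and enrichment

Feature profiles are per-feature z-scored log2 vectors concatenated across
the transcript and protein layers (features quantified in both). t-SNE uses
perplexity 20, at most the first 50 PCA components, and 15 repeats seeded
`base_seed + i`; the "exaggeration 4" setting is applied as the
early-exaggeration factor, its common meaning in t-SNE implementations.
Per-run cluster labels come from DBSCAN with a scale-free radius (the 90th
percentile of 5-NN distances; min cluster size 5) — absolute t-SNE
coordinates are meaningless, so the radius must be data-driven. Stability
is the mean pairwise adjusted Rand index of run labels; runs are aligned to
the first run by best overlap and combined by per-feature majority vote.
The largest consensus cluster plus density noise is the background stream;
remaining clusters are directed by the sign of their members' mean
fetal-minus-adult log2 difference (group 1 up-in-fetal, group 2 down). The
density rule is a reproducible stand-in for the visual cluster selection
such embeddings usually receive, and is labeled as such in the outputs.

Enrichment is a one-sided hypergeometric test per annotation term
(intersected with the universe; terms under 3 members skipped) with BH FDR.
The default universe is the features quantified in ≥ 2 layers, mirroring
the integrated scope. Orthologue-based network enrichment against external
databases is out of scope; the GMT-based test is local and self-contained.

## Biomarker panel search

Wilks' Λ = det(W)/det(T) from within-group and total scatter matrices,
with Rao's F approximation — exact for two groups, and reducing to one-way
ANOVA for single features (asserted against an independent ANOVA oracle).
Near-singular scatter (condition number > 1e12, e.g. duplicated panel
members) raises an error naming the features. Testing all combinations of
1–6 features over thousands of proteins is combinatorially impossible, so
the search restricts to the top `pool_size` (default 20) features by
univariate ANOVA p; within the pool all Σ C(K, s) combinations are tested.
The restriction is recorded in the result metadata, and the synergy flag
(panel p below every member's singleton p) is the quantity of interest —
no multiplicity correction is applied to panel p-values beyond a BH column
for transparency. Note the univariate screen can exclude purely
synergistic pairs whose marginal signals vanish; validation of the synergy
machinery therefore uses a pool covering all candidate features.

## Validation problem sizes

The acceptance checks run at these sizes, chosen to make each property
measurable with comfortable statistical margins while keeping a full
validation pass in tens of seconds: 10⁴ random p-vectors for the Fisher
oracle; 200 random instances (≤ 8 pathways, ≤ 10 entities) for exact
assignment-cap optimality; 1000 null pathways (999 permutations each) for
calibration; 20 seeded end-to-end runs at the default study conditions
(240 genes, 60 metabolites, 12 pathways, 2000 permutations per pathway
p-value — the permutation floor 1/2001 is orders of magnitude below any
null pathway's combined p, so the ranking outcome is unaffected by using
fewer than the 10 000-permutation default); 100 random 300-nt sequences
and a 50-protein/40-transcript fixture for proteogenomics; 2000 null
features against a 20 000-draw Monte-Carlo oracle for differential
calibration; and 15-run t-SNE on 150 profiles in 3 planted clusters.

## Known limitations

* The per-layer pathway test is competitive and exchangeable-null; it does
  not model inter-feature correlation, which inflates significance on real
  data where pathway members co-express.
* Fisher's method assumes independent layers; shared samples induce
  dependence, so combined p-values are calibrated only under the
  generator's independence. Treating layers as independent observations is
  the method's stated premise, not a verified property of real data.
* The assignment-cap objective and the evidence criterion for proteome
  filtering are interpretations of under-specified procedures; both are
  parameters and their defaults are documented above.
* Cluster boundaries on the t-SNE plane depend on the density parameters;
  stability below `stability_min` (default 0.8) is flagged, not fatal.
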