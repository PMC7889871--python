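# Methods

## Model overview

`commscape` scores directed communication between cell groups through
curated-style ligand-receptor rules. The pipeline is:

1. **Over-expression pre-filter.** For every gene shared between the
   expression matrix and the database, a one-sided Wilcoxon rank-sum test
   of each group against all other cells flags up-regulated signaling
   genes at raw p < 0.05 (no multiple-testing correction: this step is a
   permissive gate, significance comes from the permutation test). An
   interaction enters scoring if any of its ligand or receptor subunits is
   flagged somewhere (`de_strictness="all"` requires every subunit).
   Constant genes short-circuit to p = 1.
2. **Robust group summaries.** Per-gene, per-group expression is Tukey's
   trimean (type-7 quartiles). The trimean is zero unless a gene is
   detected in more than 25% of a group's cells, which is the mechanism
   that suppresses dropout-driven false communication.
3. **Mass-action probability.** The tensor entry P[i,j,k] multiplies a
   Hill response of the ligand-receptor product, agonist/antagonist
   factors of both sender and receiver, and optionally the population
   factor n_i n_j / n². Complex expression is the geometric mean of
   subunit trimeans and is exactly zero when any subunit is zero or
   missing from the matrix (missing cofactor genes, by contrast, are
   dropped from their set mean — conservative for required parts,
   permissive for optional modulators). Agonist/antagonist factors default
   to 1 when the cofactor set is empty.
4. **Permutation significance.** Cell group labels are permuted M times;
   each permutation reuses one shuffle for all pairs (preserving
   cross-pair correlation under the null) and recomputes trimeans and the
   full model. p = #{m : P⁽ᵐ⁾ ≥ P_obs}/M: the upper tail, so strong
   observed communication is significant; the observed statistic is not
   added to the permutation set, giving p a resolution of 1/M with 0
   attainable. (A lower-tail variant is available via `tail="lower"` for
   comparison, but it marks weak entries, not strong ones.)
5. **Pathway aggregation.** A pathway's K × K network sums the
   probabilities of its significant pairs; all-zero pathways are dropped.
   No normalization is applied across receivers — entries are interaction
   strengths, not a probability distribution.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `Kh` | 0.5 | Hill half-saturation; assumes input normalized to ~[0, 1] (the container warns above `range_bound=10` and offers max-rescaling) |
| `hill_n` | 1 | Hill exponent, applied to the product L·R with denominator Khⁿ (standard Hill form) |
| `M` | 100 | permutations; p-value resolution 1/M |
| `alpha` | 0.05 | significance threshold for DE filter and permutation gate |
| `population_size` | on | multiply by n_i n_j / n²; disable for sorting-enriched data |
| `min_cells` | 10 | groups below this size are excluded (trimean and permutation are unstable for tiny groups) |
| `seed` | 0 | drives the permutation stream; results are bit-reproducible |

Significant-pair sets are fairly insensitive to `Kh` in [0.25, 0.75] and
`hill_n` in {1, 2} because the permutation test compares each entry to its
own null rather than to an absolute cutoff.

## Network analyses

* **Centralities.** Weighted out-/in-degree identify dominant senders and
  receivers (their sums both equal the pathway's information flow — a
  conservation law the tests enforce). Freeman flow betweenness (total
  max-flow between other ordered pairs that depends on a node) identifies
  mediators; Stephenson–Zelen information centrality, computed per
  connected component of the symmetrized network (A + Aᵀ)/2 via
  C = (L + J)⁻¹, identifies influencers; isolated nodes score 0.
  Relative-importance columns are per-measure min-max scalings to [0, 1].
* **Patterns.** The masked tensor is collapsed to a groups × signals role
  matrix (outgoing: sum over receivers; incoming: sum over senders; the
  two share their grand total). Frobenius NMF takes the best of 10 random
  initializations; zero rows/columns are removed and re-inserted as zero
  loadings. Rank selection builds a consensus over repeated factorizations
  (multiplicative updates with a modest iteration budget, so
  init-dependence probes stability) and tracks the cophenetic correlation
  and consensus silhouette against their running maxima: the selected rank
  is the last one before either metric drops by more than 0.025. A drop in
  either suffices — on small near-binary consensus matrices the cophenetic
  correlation is too insensitive for a both-metrics rule to ever fire —
  and without any drop the default of 5 patterns is used. Loading tables
  are min-max normalized per W-row / H-column (all-equal non-zero rows map
  to 1, zero rows to 0) and thresholded at 0.5 ("alluvial": one pattern
  per group/pathway) or 1/R ("dotplot"); normalization precedes
  thresholding. Contribution scores multiply W by H on the original scale
  after zeroing dot-plot-suppressed entries.
* **Similarity and manifold.** Functional similarity is the Jaccard
  overlap |∩|/|∪| of positive directed edge sets (1 for two empty
  networks by convention; a symmetric-difference denominator variant
  exists behind a flag but is unbounded and undefined at identity, so it
  is not the default). Structural dissimilarity combines, with weights
  (0.45, 0.45, 0.10): the Jensen–Shannon divergence of graph-averaged
  node-distance distributions, the difference of network node dispersions
  (generalized JSD of per-node distance distributions over log(d+1)), and
  the JSD of α-centrality profiles of the binarized graph and its
  complement. Conventions for small, possibly disconnected graphs:
  distances on the undirected binarized graph; unreachable pairs placed
  one past the diameter so each node's distribution is proper; edgeless
  graphs get dispersion 0; α = 0.9/λ_max with a ones exogenous vector,
  profiles normalized to sum 1 and sorted descending with zero-padding
  when node counts differ. Similarity matrices are smoothed by the shared
  k-nearest-neighbor graph (k = √N rounded) via the symmetrized product
  Gs·S, embedded in 2-D by UMAP (precomputed distance 1 − min-max-scaled
  similarity, n_neighbors = k, min_dist = 0.3, fixed seed), and grouped by
  consensus k-means over k = 2..10 with entries < 0.3 pruned and the group
  count read from the largest Laplacian eigen-gap (second-largest behind a
  flag). Joint embeddings of several datasets tag each point with
  (dataset, pathway); functional mode requires identical ordered group
  sets across datasets.
* **Condition comparison.** Shared pathways are ranked by signed
  information-flow difference and categorized on/off (flow below an
  absolute tolerance on one side), unchanged (within 5% relative
  tolerance), or increased/decreased. The multi-subunit false-positive
  metric counts a single-gene-pair prediction as one false positive when
  it names some but not all subunit pairs of a multi-subunit interaction
  for that source/target (a prediction list covering the complete complex
  is not penalized); the denominator is all predictions by default, or
  only multi-subunit-relevant ones. Subsampling robustness draws uniform
  stratified subsamples (group proportions preserved — a deliberate
  simplification of density-preserving sketching), re-runs inference end
  to end, and scores the significant (source, target, pair) set against
  the full-data run: TPR over full-data edges, FPR over the remaining
  tested entries, ACC overall.

## Label-free grouping

When no labels are given, cells are clustered by building a shared
nearest-neighbor graph from their k = 20 nearest neighbors in a supplied
low-dimensional embedding (edge weight = shared-neighbor fraction) and
running Louvain community detection. With an explicit resolution one run
decides; otherwise Louvain is run over a resolution grid, and the group
count is chosen by the same consensus/eigen-gap machinery used for
pathway grouping, with final labels from cutting the consensus dendrogram.

Optional smoothing by protein-protein-interaction network propagation
(random walk with restart, restart probability 0.5, per-cell mass over
PPI genes conserved) is off by default: the core model is self-contained
without it, and it is provided for sparse data where complex subunits
drop out.

## Synthetic study conditions

The generator emulates a small unsorted single-cell experiment: 4 groups
× 50 cells, 50 interactions over 5 pathways with exactly 30%
multi-subunit receptors and 20% cofactor-bearing pairs, log-normal
baseline centered at 0.1 (so a ten-fold planted effect sits near 1.0, the
upper Hill regime for Kh = 0.5). Baseline genes are detected in 15% of
cells — real log-normalized single-cell matrices are mostly zeros, and
this keeps unexpressed genes below the trimean's one-quarter detection
threshold, which is precisely the regime the robust mean is designed for.
Planted communications elevate ligand subunits in the sender group and
receptor subunits (plus co-stimulatory genes) in the receiver group, with
signal surviving independent Bernoulli dropout at rate 0.2 (an
expression-dependent dropout option exists). Ground truth is returned for
scoring. Calibration runs use a dense continuous baseline (expressed
fraction 1.0, dropout 0) because permutation-test calibration is a
statement about continuous exchangeable statistics; on sparse data ties
make the test conservative, which is a separate, deliberate property.

What passing tests on this generator do **not** show: behavior under UMI
count noise, library-size variation, batch effects, doublets, or
expression-magnitude-correlated dropout — the generator plants clean
group-specific signals and is a functional test bed, not a realistic
scRNA-seq simulator.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 200 cells, 50 pairs,
100 permutations, 5–10 seeds per stochastic check — sizes at which every
stage completes in seconds while the statistical claims (binomial
intervals, recovery rates) remain meaningful. All randomness flows
through explicit seeds; repeated runs are bit-identical, including the
CLI pipeline outputs.

## Known limitations

* Expression-level proxies: protein abundance, secretion, diffusion and
  spatial proximity are not modeled; communication scores are
  transcriptome-level hypotheses.
* The permutation null conditions on the observed group sizes; groups
  below `min_cells` are excluded rather than modeled.
* Hill cooperativity (`hill_n` ≠ 1) applies one exponent to the product
  L·R; per-factor cooperativity is not separable from the data.
* Functional similarity requires identical group sets; structural
  similarity binarizes away edge weights.
* UMAP coordinates are layout, not metric truth: the duplicate-network
  control checks relative, not absolute, distances (UMAP's min_dist floor
  prevents exact coincidence even at similarity 1, so the check uses the
  median duplicate distance against the 5th percentile of all pairwise
  distances).
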