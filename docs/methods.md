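# Methods

## The quantity being measured

Given a gene set and a phenotypic group of samples (e.g. epithelial vs
mesenchymal cell lines, or two patient cohorts), `coexhier` asks: *how
hierarchically organized is the collective expression of these genes in
this group?* The answer is a single number per (gene set, group), the
normalized cophenetic correlation coefficient CCC_norm, with a bootstrap
standard error.

The chain of definitions:

1. **Network.** Nodes are the genes of the set present on the platform.
   The edge weight between genes *i* and *j* in group *G* is

       l_ij = | Σ_{k∈G} (e_ik − μ_i)(e_jk − μ_j) / (σ_i σ_j) |

   with μ and σ the within-group per-gene mean and standard deviation and
   the sum running over the group's samples. With the sample-sd convention
   (see below) this is (n−1)·|r_ij| for Pearson's r, so the network is a
   fully connected, undirected co-variation-strength graph; correlation
   sign is deliberately discarded.

2. **Distance.** The distance between two nodes is the Euclidean commute
   time distance (ECTD): the square root of the expected round-trip length
   of the natural random walk on the weighted graph. It is computed through
   the Moore–Penrose pseudoinverse L⁺ of the graph Laplacian:
   effective resistance r_ij = L⁺_ii + L⁺_jj − 2L⁺_ij and
   ECTD_ij = √(Vol·r_ij), where Vol = Σ_ij W_ij is the total weighted
   degree. ECTD shrinks when many independent paths connect two genes and
   grows when paths lengthen, which is what makes it an informative
   clustering distance for networks. The effective resistance itself is
   available as an alternative metric for sensitivity analysis.

3. **Tree fit.** The distance matrix D is clustered with average linkage
   (UPGMA). The cophenetic distance T_ij is the merge height first uniting
   genes i and j. The CCC is the Pearson correlation between the N(N−1)/2
   off-diagonal D entries and the corresponding T entries: 1 exactly when
   D is an ultrametric (i.e. perfectly tree-like), lower as the hierarchy
   degrades.

4. **Normalization.** Raw CCC values are high even for unstructured
   networks, because commute-time matrices carry node-level (degree)
   structure that any dendrogram partially fits. Each measurement is
   therefore normalized against a shuffled null: the upper triangle of D is
   permuted uniformly at random (conserving the multiset of distances),
   each of 10 shuffled matrices is re-clustered and scored, and

       CCC_norm = (CCC − CCC_rand) / (1 − CCC_rand)

   with CCC_rand the mean over the shuffles. CCC_norm ≈ 0 means no
   hierarchy beyond chance; 1 means perfectly tree-like; negative values
   are possible. An alternative null (`null_shuffle="weights"`) permutes
   the network's edge weights and recomputes distances, for sensitivity
   analysis; the distance-shuffle is the default because it is the
   operative definition of the statistic.

5. **Uncertainty.** The bootstrap treats the group's empirical sample
   distribution as the population: each of B = 100 replicates redraws the
   n sample columns with replacement and reruns the entire pipeline,
   including fresh null shuffles. The SE is the sample SD of the replicate
   CCC_norm values; the point estimate always comes from the unresampled
   group. Two groups are compared with a one-sided paired-difference
   bootstrap p-value, p = (1 + #{Δ_b ≤ 0})/(B + 1) — the add-one rule
   respects the B-replicate granularity, giving a floor of ≈0.0099 at
   B=100 — and with a two-sample Kolmogorov–Smirnov test on the two
   replicate distributions (asymptotic p-value; exact small-sample
   corrections are immaterial at B=100). A `percentile` p-value variant
   (plain fraction of differences ≤ 0) is available.

6. **Specificity control.** To check that an observed group contrast is a
   property of a particular gene set and not of the transcriptome at
   large, `random_geneset_specificity` draws (by default) 100 random sets
   of k = 83 genes uniformly without replacement from the expression
   matrix's full gene universe, scores each with the one-sided bootstrap
   p-value, and reports the raw count significant at α = 0.05. No
   multiple-testing correction is applied to this count — it is itself the
   calibration quantity (≈ α·100 expected under the null).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `metric` | `ectd` | node distance; `resistance` available as robustness check |
| `n_rand` | 10 | shuffled nulls per CCC normalization |
| `n_boot` (B) | 100 | bootstrap replicates per group |
| `alpha` | 0.05 | significance level in the random-set control |
| `k` | 83 | random-set size (typical analyzed-gene-set size) |
| `epsilon` | 0 | optional uniform weight added to rescue exact-zero-weight degeneracies |

All quantities are unit-agnostic: the network construction standardizes
each gene internally, so CCC and CCC_norm are invariant to per-gene affine
transforms of expression, to uniform rescaling of the whole matrix, and to
gene/sample ordering (tested).

## Numerical choices

- **SD convention.** The within-group σ uses the sample convention
  (denominator n−1). The alternative (population, n) rescales every edge
  weight by the same constant; ECTD, CCC and CCC_norm are all invariant to
  uniform weight rescaling, so the choice cannot affect results. It is
  documented and tested rather than configurable.
- **Pseudoinverse.** L⁺ via symmetric eigendecomposition, inverting only
  eigenvalues above 1e−10 × λ_max. For a connected graph exactly the
  constant eigenvector is dropped; a second eigenvalue under the cutoff
  means the positive-weight graph is disconnected and the computation
  refuses (commute times would be infinite) rather than regularizing
  silently. `build_network(epsilon=...)` exists for deliberately
  degenerate inputs.
- **Zero-variance genes.** The edge weight is undefined at σ = 0. Genes
  constant within a group are flagged at subset time, excluded before the
  network is built, and recorded in the result's provenance. Inside a
  bootstrap replicate, genes made constant by the resample are dropped for
  that replicate; a replicate retaining fewer than 3 genes is redrawn (at
  most 10 times, then an error).
- **Ties in average linkage.** The lowest-index cluster pair merges first
  (scipy's deterministic order), so dendrograms are reproducible across
  runs and platforms. Shuffled distance matrices are legal clustering
  input even though their merge heights may invert.
- **Degenerate CCC.** Zero variance among the off-diagonal distances (or
  cophenetic heights) raises an error instead of propagating NaN, so a
  single degenerate bootstrap replicate cannot silently poison a mean.
- **Hot loops.** The shuffle-null and bootstrap loops call scipy's
  cophenetic-distance C kernel directly (with a public-API fallback),
  bypassing per-call linkage re-validation; equivalence with the public
  wrapper is tested.
- **Reproducibility.** Every source of randomness descends from one
  integer seed via `numpy` `SeedSequence` substreams: the point estimate
  and each bootstrap replicate get independent children, and the CLI
  derives an independent substream per (gene set, group), recorded in the
  output tables. Identical config + seed reproduces byte-identical tables.

## What the synthetic generator emulates — and what it does not

Real cohorts for this kind of analysis are microarray expression matrices
(dozens of samples, gene sets of ~80 genes). The generator replaces them
with draws from a model in which hierarchy is the controlled ground truth:
a random binary gene tree whose nodes carry i.i.d. Exp(1) variance
increments induces a covariance Σ_tree (covariance between two genes =
total increment on shared ancestors; positive definite by construction
because every leaf has its own increment), normalized to unit diagonal and
mixed as Σ = h·Σ_tree + (1−h)·I. The hierarchy strength h ∈ [0,1] spans a
flat null (h=0) to a perfectly tree-structured group (h=1); samples are
i.i.d. multivariate normal. Default scales are 80 genes and 25 samples per
group, matching the targeted cohorts' order of magnitude.

The generator does **not** emulate microarray probe effects, batch
structure, heavy-tailed or count noise, outlier samples, or real gene
symbols. Passing tests on this model therefore demonstrate that the
pipeline recovers tree-structured covariance from moderately sized
multivariate-normal samples — not that any particular real dataset is
hierarchical. Two empirical features of the method do carry over and are
worth knowing: CCC_norm sits well above 0 (~0.8) even for h=0, because
commute-time matrices are intrinsically partially tree-fittable, so only
*contrasts* between groups are interpretable; and the bootstrap SE of
CCC_norm at 25 samples (~0.02–0.03) is of the same order as the h=0.9 vs
h=0 contrast itself (~0.05–0.1), so single-dataset contrasts at this
sample size sit near the detection limit — the direction of the contrast
is recovered essentially always, while the one-sided bootstrap test at
α=0.05 reaches roughly 65–70% power under the default generator settings.

## Problem sizes used in the checked examples

The test suite and the acceptance summary use: the 80-gene / 25+25-sample
contrast above (50 seeds for direction recovery, 20 seeds at B=100 for
test power); a 120-gene universe with 20+20 exchangeable samples for the
null calibration of the 100-random-set control, run at B=20 (the p-value
granularity 1/21 still resolves α=0.05) so that 20 independent reruns of
the full control are tractable on one CPU; and graphs of N ≤ 30 for the
closed-form and oracle cross-checks.

## Known limitations

- Dense linear algebra throughout: O(N³) per network for the
  eigendecomposition. Fine for gene sets (N ≲ 500); not intended for
  whole-transcriptome networks.
- The entry-shuffle null conserves distances but not their metric
  consistency; this is intrinsic to the statistic's definition, not a bug.
- The absolute value in the edge weight makes coherent activation and
  mutual exclusion indistinguishable; interpreting *why* a group is more
  hierarchical requires looking at the signed correlation structure
  separately.
- Probe-to-gene collapsing, normalization, and cohort curation are
  upstream of this package by design.
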