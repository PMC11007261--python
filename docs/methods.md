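# Methods

This note documents the statistical procedures, the generative model
behind the synthetic data, the numerical conventions, and the design
choices that were genuinely open.

## The analysis chain

The package operationalizes one question — do host factors structure a
host-associated microbiome, and does community dissimilarity
recapitulate host phylogeny? — as a chain of distance-matrix analyses.

**Beta diversity.** Four metrics span the taxonomy/phylogeny and
presence/abundance axes: Jaccard (presence only), Bray–Curtis
(abundance), unweighted UniFrac (presence on a shared microbial tree),
weighted UniFrac (abundance on the tree). The contrast among them is
itself informative: effects loading on deep microbial clades move the
UniFrac metrics relative to the taxonomy-based ones. Weighted UniFrac is
unnormalized by default; the normalized variant is a flag, since amplicon
platforms differ and the choice is rarely reported.

**Explanatory distances.** Host genetics: Kimura 2-parameter distance
from an alignment, with the Jin–Nei gamma-rate correction
(shape 3 by default); sites with gaps or N are deleted pairwise, and a
saturated pair (log argument ≤ 0) is an error rather than a clamped
value, because clamping distorts the rank structure that Spearman Mantel
tests consume. Alternatively, any precomputed genetic matrix or a host
tree's patristic distances can stand in. Geography: haversine distance on
a sphere of radius 6371.0088 km; ellipsoidal refinements are irrelevant
at the rank level. Diet and altitude: single-column Gower distances
(0/1 mismatch for categories, range-normalized absolute difference for
numbers). Population-level matrices are expanded to sample level by
assigning each pair its populations' distance.

**Permutation inference.** The Mantel statistic is the Spearman (default)
or Pearson correlation of the unfolded upper triangles; the null
distribution comes from simultaneous row/column permutation of the first
matrix. Because permuting a hollow symmetric matrix permutes the multiset
of its off-diagonal entries, rank transformation is done once and the
ranked matrix permuted — equivalent to re-ranking every permutation and
much cheaper. The partial Mantel test uses the residual method: both
rank-transformed unfolded matrices are regressed on the unfolded
controls, the statistic is the correlation of the residual vectors, and
permutation shuffles the first residual vector refolded to a matrix.
This is the dominant published implementation of the partial test; when
the controls explain a matrix completely the result is defined as r = 0,
p = 1. MRM is OLS on unfolded vectors with R² (one-sided) and per-
coefficient |t| (two-sided) permutation p-values obtained by permuting
the response matrix. PERMANOVA uses the Huygens decomposition
(SS_total = Σ_{i<j} d²_ij / n, SS_within summed per group) and permutes
group labels. All permutation p-values use the add-one convention
p = (#{≥ observed} + 1)/(n_perm + 1), hence p ∈ [1/(n_perm+1), 1];
exhaustive enumeration replaces sampling when requested on small inputs.
Pairwise PERMANOVA and Dunn post hoc p-values are Benjamini–Hochberg
adjusted — the adjustment procedure is an assumption of this package, as
published reports usually state only "adjusted".

**Co-dendrogram congruence.** Samples are collapsed to one profile per
population either as the mean of relative-abundance rows (each sample
normalized first, so depth differences do not weight samples) or as a
randomly picked member sample, repeated (default 100×) to expose
within-population heterogeneity. UPGMA clusters the population-level
beta matrix (merge height = half the average-linkage distance; ties break
on the lexicographically smallest representative pair, making the tree
deterministic). Congruence with the host phylogeny is the Robinson–Foulds
distance on unrooted topologies, normalized by its maximum 2(n−3) for
resolved trees. Significance compares the observed (or mean, in
random-pick mode) RF against randomized topologies built by uniform
random pairwise coalescence with randomly permuted labels;
p = (#{RF_random ≤ RF_observed} + 1)/(n_random + 1), so the alternative
is *more congruent than random*. At small population counts the RF
distribution is coarse (multiples of 1/(2(n−3))), which makes the test
somewhat conservative: under the null generator its empirical size at
α = 0.05 is ≈ 0.03 with 8 populations (measured over 1000 replicates).

**Subsampling sensitivity.** Host genetic data typically come from fewer
individuals than microbiome samples, so the sensitivity protocol redraws
(default) 100 subsamples of three samples per population (with
per-population overrides), recomputes the beta matrix, reruns the chosen
test, and reports the distribution of statistics and the fraction
significant at α = 0.05. Each subsample index gets an independent seed
stream derived from (seed, index), so the schedule does not depend on
execution order.

**Networks.** Taxa occurring in fewer than 5 samples are dropped, the top
100 by mean relative abundance kept, and edges drawn where the Pearson
correlation of relative abundances satisfies |r| > 0.6 with two-sided
t-test p < 0.05 (raw by default; BH optional; a centered log-ratio
transform with pseudocount 0.5 is available for compositionality-aware
analysis). Modules come from greedy modularity maximization (isolated
nodes are singletons); Zi is the within-module degree z-score (0 when the
module has < 3 members or no spread), Pi = 1 − Σ_m (k_im/k_i)², and roles
use the conventional cuts Zi > 2.5, Pi > 0.62. Relative abundances are
compositional: a dominant taxon's relative abundance necessarily
anti-correlates with rising totals elsewhere, so Pearson-on-proportions
networks contain closure artifacts by construction — the stated threshold
rule is implemented as the reproducible default, not endorsed as immune
to them.

## The synthetic generator

For taxon i in population j the latent log-abundance is

    mu_ij = b_i + sigma_phylo * g_i(j) + sigma_diet * delta_i * I(diet_j = A)

and sample s of population j draws counts ~ Multinomial(depth,
softmax_i(mu_ij + eps_is)) with eps_is ~ Normal(0, sigma_noise²).

- g_i is an independent Brownian-motion realization on the host tree
  (a Yule tree scaled to root height 1), so community similarity decays
  with host phylogenetic distance — precisely the signal the Mantel and
  co-dendrogram tests target.
- The diet covariate is clade-conserved on the host tree: one basal clade
  closest to the requested split fraction is diet A; altitude is drawn
  around diet-specific means (default 3200 m vs 900 m, sd 400 m),
  deliberately confounding altitude with diet the way high- and
  low-elevation host clades are confounded in real transect designs.
  Coordinates are uniform in a configurable bounding box (default a
  ~1300 × 2800 km region).
- delta_i marks diet-responsive taxa. In "deep" mode they are the leaf
  sets of 1–3 microbial clades whose stem nodes sit in the oldest
  quartile of internal-node ages (~10% of taxa by default); in "shallow"
  mode the same number of scattered singleton leaves.
- The baseline b_i has two deliberate structures rather than being pure
  iid noise. First, it couples to terminal branch length (coefficient 1.5
  on the standardized lengths plus Normal(0, 0.5) residual): short
  terminal branches mark fine-scale variants of abundant lineages, and in
  real ASV data those are exactly the rare, detection-boundary taxa.
  This places presence/absence sampling noise on short branches, where
  phylogenetic metrics discount it. Second, diet-responsive taxa are
  offset downward by sigma_diet + 1: a diet-obligate clade is rare or
  absent in hosts that lack the diet and ordinarily abundant in hosts
  that have it, so the diet effect reaches presence/absence metrics as
  joint toggling of whole clades (deep shared branches), not only
  abundances. With both structures, the directional property that a
  deep-clade diet effect loads on unweighted UniFrac more than on Jaccard
  is reproduced in ~95% of replicates at the sizes used in the acceptance
  experiments; with iid tree-independent baselines it is *not*
  reproducible at all (win rates 0.2–0.45 across wide parameter ranges),
  because individual clade members then toggle independently on random
  terminal branches and UniFrac's branch weighting only adds variance.
  Under the null (sigma_phylo = sigma_diet = 0) both structures live
  entirely on the taxon side, so samples remain exchangeable across
  populations and test calibration is unaffected.

What the generator does **not** emulate: chimeras and primer bias,
zero-inflation beyond multinomial sampling, within-population spatial
structure, taxonomy (names are abstract), and realistic 16S sequence
evolution. Passing recovery tests therefore demonstrates statistical
correctness of the chain, not robustness to those real-data features.

### Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| n_populations / samples_per_population | 12 / 4 | study scale of a multi-population transect |
| n_taxa | 200 | desk-scale richness |
| depth | 35,701 reads | the rarefaction depth used as an even-depth target |
| sigma_phylo, sigma_diet | 1.0 | effect scales in log-abundance units |
| sigma_noise | 0.5 | within-population log-abundance noise; a free choice, reported not fitted |
| diet_split | 0.5 | fraction of host leaves in the diet-A clade |
| diet_taxa_fraction | 0.1 | fraction of microbial taxa carrying the diet effect |
| branch_abundance_coupling / baseline_sd | 1.5 / 0.5 | baseline structure described above |
| diet_rarity_offset | 1.0 | extra rarity of diet taxa without the diet |

## Problem sizes in tests and acceptance runs

Calibration runs use 8 populations × 3 samples, 40 taxa, depth 2,000,
199 permutations, and 500 randomized trees over 1,000 replicate
datasets; measured type-I error at α = 0.05: Mantel 0.034, partial
Mantel 0.044, MRM 0.046, PERMANOVA 0.049, phylosymbiosis 0.030 (the last
reflecting the RF discreteness noted above). Recovery runs use 12
populations × 3 samples at depth 2,000 with 100 taxa (phylogeny signal)
or 200 taxa (diet contrast). Presence/absence contrasts are evaluated at
depth 2,000 rather than 35,701 because the detection boundary
(depth ≈ richness × typical abundance) is where presence-based metrics
carry information; at full depth and desk-scale richness every taxon is
saturated-present and Jaccard/unweighted UniFrac are near-degenerate for
any generator of this family.

## Numerical conventions and degenerate inputs

- Spearman ranks use average-rank tie handling.
- Chao1 falls back to the bias-corrected form when no doubletons exist.
- Shannon defaults to log2 (amplicon-platform convention); base e by flag.
- A constant distance matrix is a degenerate-statistic error for Mantel;
  complete partialling returns r = 0, p = 1; an all-tied group test warns
  and returns p = 1.
- PERMANOVA's pseudo-F is infinite for perfectly separated groups; its
  permutation p remains valid and equals the partition-preserving
  fraction.
- Rarefaction uses multivariate-hypergeometric draws (uniform subsampling
  without replacement); samples below depth are dropped with a logged
  warning rather than erroring.
- UPGMA heights are clipped at 0 against floating-point underflow;
  non-ultrametric inputs still yield a deterministic ultrametric tree.
- Softmax subtracts the row maximum before exponentiation.
- Master seed → stage seed derivation hashes the stage name, so adding a
  pipeline stage never perturbs earlier stages' randomness.

## Known limitations

- The partial Mantel residual-permutation scheme, like all published
  variants, is approximate under strong spatial autocorrelation of the
  controls.
- MRM's permutation test for R² is slightly conservative on matrices with
  point-geometry structure (measured ≈ 0.03–0.05 at nominal 0.05).
- The co-dendrogram test's size depends on the number of populations
  through RF discreteness (≈ 0.03 at n = 8, approaching nominal as n
  grows).
- SparCC-style basis-variance correlation and RMT thresholding are out of
  scope for networks; the Pearson threshold rule is implemented because
  it is the only fully specified, reproducible construction.
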