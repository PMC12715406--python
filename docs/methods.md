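# Methods

This note documents the models, estimators, numerical choices and known
limitations of `coexgraph`. Everything stated here is computed by the test
suite or the acceptance script; nothing is an external empirical claim.

## Preprocessing

Counts are filtered (mitochondrial `MT-`/`mt-` and spike-in `ERCC-` prefixes
removed, regex configurable; genes detected in < 10 observations removed;
cells with < 200 detected genes removed — spots are never removed, preserving
the spatial lattice) and normalized as `log(1 + count · target_sum /
library_size)` with `target_sum = 10 000` (the common library-size convention;
the value is configuration, not substance — every information metric is
invariant to it up to binning). Spatial spots with zero library size are kept
(all-zero normalized row) but excluded from MI estimation. Preprocessing is
idempotent. Gene alignment across modalities is exact-match intersection in
lexicographic order; a `case_insensitive` flag supports cross-species-style
symbol matching.

## Stage I: highly confident pseudo-labels

- Neighbor-label entropy is computed in bits (base 2); the retention threshold
  (median of positive entropies) is base-invariant.
- The prose rule "predominantly different" is operationalized as a strict
  majority check: a spot is kept only if > half its neighbors share its label,
  in conjunction with the entropy rule. Isolated spots are peripheral.
- Domain subgraphs smaller than the lattice neighbor count (6 for a hexagonal
  Visium-style array, 4 for a square array) are dropped.
- Hop distances come from all-pairs shortest paths on the unweighted subgraph
  (`scipy.sparse.csgraph`); eccentricity, radius and center follow the standard
  graph-theoretic definitions.
- "Distance to the center set" is the minimum over center vertices. The HC
  rule `d(u, ψ) < 0.6·r` is strict, which would select nothing when r = 0;
  center vertices are therefore always included, so singleton components still
  yield HC spots.
- Spot neighbor graphs are built from coordinates: spots within 1.3× the
  minimal positive spot spacing are linked, capped at 6 neighbors — on array
  (row, col) coordinates this reproduces the hexagonal/square lattice without
  needing platform metadata.
- The default spatial backend is Leiden community detection on the union of an
  expression-PCA kNN graph and the spatial-neighbor graph, with the resolution
  bisected to match a requested domain count; any callable
  `(dataset, n_clusters) -> labels` can be injected, and user labels pass
  through untouched. Cells mirror the spot rule on an expression-PCA kNN
  graph. Dedicated spatial clustering tools (SpaGCN, Seurat and the like) work
  as injected backends; the HC selection is deliberately robust to the choice,
  so the default avoids a heavyweight dependency.

## Information metrics

All metrics are in nats internally; thresholding operations are
unit-invariant.

Two estimator families are provided:

- **kNN estimators** (`estimator="knn"`): KSG type-1 for continuous pairs,
  Ross for continuous–categorical, Frenzel–Pompe for CMI with a continuous
  conditioner, and exact stratification I(X;Y|L) = Σ_l p(l) I(X;Y|L=l) for a
  categorical conditioner. The continuous-pair estimator uses the mixed
  discrete–continuous correction: points whose k-th neighbor distance is
  exactly zero (probability atoms, e.g. the zero counts of sparse data) use
  the atom multiplicity as local k and zero-radius marginal counts. This keeps
  independent zero-inflated variables near zero MI, where jittered KSG
  produces large spurious values. k = 3 by default; negative raw estimates are
  clamped to zero.
- **Equal-frequency binned plug-in estimators** (`estimator="binned"`, the
  pipeline default, 8 bins): each gene is quantile-binned (tied values always
  share a bin) and MI/CMI are plug-in values with the Miller–Madow bias
  correction. Rationale: after library-size normalization, a normalized value
  is — within one count level — an invertible function of the observation's
  library size, so any estimator that resolves arbitrarily fine differences
  reads library size as information shared between *all* gene pairs. Binning
  at the count-level scale quantizes this channel away while preserving the
  biological signal. The binned path is also ~10× faster on the all-pairs
  stage. The kNN path remains available and is the one calibrated against
  closed forms in the tests.

The redundancy/complementarity inequality (Red < Comp ⟺ both conditional
relevances exceed the plain ones) is an exact identity of the interaction
information; the test suite verifies the equivalence on 1000 random discrete
joint distributions with exact plug-in values.

Composite metrics are w·SC + (1−w)·SRT with w = 0.5 by default (the weighting
is not prescribed; equal weight is the neutral choice and is exposed in
configuration). w = 0 / w = 1 select single-modality modes.

## Gene clustering

- Retention keeps genes in the top q = 0.8 fraction of relevance in every
  available modality (`ceil(q·n)` ranks per modality, intersected).
- The maximum spanning tree is Prim's algorithm with deterministic
  lexicographic gene-pair tie-breaking; tests verify optimality against
  exhaustive Prüfer-sequence enumeration on 7-vertex graphs.
- RRI = Red / max(min(Rel_i, Rel_j), Comp); a zero denominator yields +∞
  (edge never cut). Edges with RRI ≥ the threshold are preserved — ties break
  toward preservation so the cap at threshold 1 exactly reproduces the two
  separation conditions (Red < Comp, or Red < min Rel).
- The hierarchy is the HDBSCAN-style condensed tree with λ := RRI: removing
  edges in increasing-RRI order, a split with both sides ≥ `min_size` (5)
  kills the parent and births the children; a smaller side is fall-out (its
  genes leave, the cluster continues); clusters surviving to the cap end at
  λ = 1. Stability(C) = Σ_members (λ_leave − λ_birth). Excess-of-Mass selects
  a cluster iff its stability is at least the sum over its selected
  descendants, except that a root that ever splits is never selectable (its
  birth at λ = 0 is an artifact of the sweep origin and would otherwise always
  dominate — the standard condensed-tree convention). Genes that fell out
  above the selected antichain are merged back along the MST by label
  propagation in decreasing-RRI order, so every gene lands in exactly one
  final cluster and no final cluster is smaller than `min_size`.
- Benchmark-style comparisons often fix a target cluster count; since EOM is
  otherwise automatic, an optional `target_n_clusters` picks the hierarchy
  antichain whose size is closest to the target (greedy expansion by stability
  gain, ties toward higher total stability).

## Interaction networks

Θ = w·corr(SC) + (1−w)·corr(SRT) (zero-variance genes get zero correlations
with a warning). The redundancy (MI) table has no natural diagonal and no
upper bound, so it is mapped onto the Gaussian-equivalent correlation scale:
under a Gaussian copula I = −½ log(1−r²), hence |r| = √(1−e^(−2I)) ∈ [0, 1)
with unit diagonal — the natural surrogate covariance for the copula graphical
model, and bounded so that near-duplicate gene pairs cannot push entries past
the valid correlation range. The
surrogate is sign-adjusted entrywise by sign(Θ) (sign(0) := 0, diagonal kept).
Because the result need not be positive definite, it is diagonally loaded to
an eigenvalue floor of 10⁻³ before the graphical lasso (scikit-learn solver;
α = 0.1 default, exposed; α = 0 is the direct inverse), with retries at floors
10⁻² and 10⁻¹ for ill-conditioned panels. Partial correlations use the
standard form Φ_ij = −Λ_ij/(√(Λ_ii Λ_jj)+ε), ε = 10⁻⁶, diagonal set to 0;
ranking uses |Φ|, so the sign convention cannot affect order. Condition
contrasts are entrywise |Φ_A − Φ_B|; with per-condition replicates a paired
permutation test (condition swap within pairs) gives p-values, otherwise a
reference contrast (e.g. healthy-vs-healthy) supplies an empirical null;
Benjamini–Hochberg adjustment flags pairs at adjusted p ≤ 0.05; the
permutation scheme is a generic paired design, documented as such.

## Pattern query

Levels map to the {95, 85, 75, 65, 35}th percentiles (linear interpolation) of
per-gene mean normalized expression. The pseudo-gene is that piecewise-
constant profile plus Gaussian noise with sd = 0.1 × level value (noise model
and fraction are configuration; proportional Gaussian noise keeps the
pseudo-gene's signal-to-noise ratio uniform across levels). The search runs the clustering pipeline in spatial-only mode
(w = 0; the pseudo-gene has no single-cell counterpart), with the pseudo-gene
exempt from relevance retention, and returns its cluster-mates ranked by
redundancy with it.

## Evaluation metrics

Davies–Bouldin uses mean pairwise intra-cluster distances (2/(n(n−1))
normalization) and model distances between centroid vectors; singleton
clusters contribute d_i = 0 with a warning and coincident centroids an
infinite ratio. The spatial distance rasterizes each gene's expression to an
N_x×N_y grid (nearest cell, multiple spots averaged, empty cells 0) and
evaluates √((x_p−x_q)ᵀW(x_p−x_q)) with a Gaussian kernel over raster cell
locations (bandwidth 1.5 grid units, truncated at 3σ, stored sparse — the
dense kernel is infeasible at scale). ARI and NMI are contingency-table
implementations (cross-checked against scikit-learn); NMI of two identical
single-class labelings is defined as 1 (0/0 convention). The neighbor-voting
co-function AUC double-centers the distance tables (S = −½(I−M/d)·D·(I−M/d);
the single-cell table enters through the entrywise absolute value of the
Pearson distances), fuses them
with weight w, masks one third of the genes' annotation rows per fold, scores
p_tj = Σᵢ S_ti A_ij / Σᵢ S_ti with a midrank Mann–Whitney AUC, and averages
over folds; degenerate held-out terms are skipped with a warning.

## Synthetic data

The generator emulates what the method assumes of real tissue: a hexagonal
(odd-row offset, Visium-like) or square lattice partitioned into contiguous
domains by balanced compact region growing (each step extends the smallest
domain at its best-supported frontier site); cells partitioned uniformly into
types; gene modules active in module-specific domain sets and cell types
(mean × `module_effect` when active); negative-binomial counts with shape
`dispersion` (var = μ + μ²/θ). Defaults are the conditions used throughout the
tests: 16×16 hex lattice, 4 domains, 500 cells, 4 cell types, 200 genes in 4
modules of 40 plus 20 % noise genes, 8-fold module effect, θ = 10.

Choices a reader should know about:

- Per-gene baselines are log-normal (median 1 count/spot, log-sd 0.75),
  mirroring the wide dynamic range of real transcriptomes; the pattern-query
  level scale is anchored at percentiles of per-gene mean expression and is
  uninformative if all genes share one baseline.
- Every module reuses the same baseline multiset, and domain-activity groups
  receive equal contiguous domain blocks, so total active expression mass is
  balanced across domains and cell types. Without this balance, library size
  itself becomes a domain/type indicator and normalization leaks that signal
  into every gene — a real compositional effect, but one that would dominate a
  200-gene panel far more than a 20 000-gene transcriptome.
- `n_confounded_pairs` makes module pairs share domain activity while keeping
  disjoint cell types: such pairs are indistinguishable from spatial data
  alone and separable only by integrating the single-cell modality.
- What the generator does **not** emulate: within-spot cell-type mixtures
  (spot deconvolution), spatial autocorrelation beyond domain structure,
  batch effects, ambient RNA. Passing tests therefore demonstrate the
  machinery under the model's own assumptions, not performance on any real
  tissue.

## Problem sizes and determinism

The test suite and acceptance script run the full pipeline on the 200-gene /
256-spot / 500-cell fixture (≈ 13 000 gene pairs per modality after
retention), MST oracles on 7 vertices × 20 graphs, the equivalence property on
1000 joint distributions, and estimator calibration at n = 10 000. All
randomness flows from explicit seeds; reruns with the same configuration and
seed are bit-identical, and each run's manifest records parameters, versions
and sizes.

## Known limitations

- The binned estimator's Miller–Madow correction under-corrects for classes
  with very few HC observations; complementarity values in small domains are
  noisier than relevance/redundancy.
- Conditional relevance with a continuous conditioner combines three kNN
  estimates via the chain rule and inherits their biases; it is used in
  property checks, not in the clustering path.
- The EOM stability formulation and the paired permutation scheme admit
  several reasonable variants; the ones implemented are documented above and
  kept behind narrow interfaces so alternatives can be swapped in.
- With very small or very elongated spatial domains, the graph-center HC rule
  retains few spots and all label-dependent metrics for that domain degrade;
  this is inherent to the center-of-domain trust model.
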