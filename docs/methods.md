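# Methods

## Model and assumptions

`rwrfuse` integrates L omics layers measured on one shared sample set by
treating each layer as a sample similarity network and fusing the layers
through a random walk with restart (RWR) on the resulting multiplex network.
The core assumption is that samples of the same (unknown) subtype are mutual
near neighbors in at least some layers, and that diffusing similarity mass
through all layers at once recovers subtype structure that no single noisy
layer shows cleanly. The walk is linear, so the fused network is a smooth,
deterministic function of the input similarities; all stochasticity in the
pipeline comes from k-means seeding and from the synthetic generators.

### Similarity kernel

Per layer, pairwise Euclidean distances over all (standardized) features are
passed through the scaled exponential kernel
`S(x,y) = exp(−dist²/(μ·E))` with the locally adaptive bandwidth
`E(x,y) = [mean(dist(x,N_x)) + mean(dist(y,N_y)) + dist(x,y)]/3`.
The neighbor mean excludes the point itself (a self-distance of zero would
deflate the scale); ties in neighbor selection are broken by sample index so
the network is deterministic. Duplicate points get similarity 1 by the
limiting convention. Defaults: `N = 20` neighbors, `μ = 0.5`. The kernel
matrix keeps a unit diagonal.

### Multiplex coupling

- **RWRF** (plain): every inter-layer block is the identity — each sample is
  linked only to its own mirror in the other layers.
- **RWRNF** (neighbor-informed): from layer j, sample x sends weight
  `β = 0.9` to its mirror and `(1−β)/m` to the mirrors of its `m = 10` most
  similar neighbors *in layer j*, so inter-layer edges carry the source
  layer's neighborhood structure and the coupling is directed
  (`A_jl` built from layer j generally differs from `A_lj`ᵀ). With more than
  two layers each ordered pair (j, l) gets its own block built from layer
  j's neighborhoods — the natural extension of the pairwise rule.

### Transition matrix and self-loops

Within a layer the walker stays with probability `λ_j` (uniform `1/L` by
default) and moves along row-normalized similarities; it jumps to each other
layer with probability `(1−λ_j)/(L−1)` along the row-normalized coupling.
For unequal weights, `λ_j` is read as the stay probability of layer j with
the jump mass split evenly — this reduces to the standard stay/jump pair for
two layers and to `1/L` everywhere for the uniform default.

Self-similarity is **removed** before row normalization. This is a deliberate
design choice: the kernel's off-diagonal mass scales like `exp(−Θ(dist))`
and is therefore strongly layer-dependent (a 367-feature layer's affinities
can sit 20 orders of magnitude below a 131-feature layer's). A unit
self-loop competes with that mass, so keeping it makes high-dimensional
layers contribute arbitrarily little to the walk — in the multi-view
benchmark below it drove the fused NMI to 0.24 when the best single view
alone reached 0.58, inverting the method's central property. Normalizing
off-diagonal mass alone gives every layer the same total transition weight;
a row with no off-diagonal mass at all (n = 1, or an exactly duplicated
isolated sample) falls back to a self-loop so W stays stochastic.

### Restart, convergence, fusion

The iteration `p_{t+1} = (1−γ)Wᵀp_t + γp_0` uses restart probability
`γ = 0.7` and stops when the L1 difference of successive iterates falls
below `1e−10` (L1 is the natural norm for probability vectors; the cap is
1000 iterations, and non-convergence raises with the offending seed).
Restart mass is uniform over mirror nodes for RWRF; for RWRNF the seed's
layer gets `α = 0.9` and the rest flows through the coupling rows. A
closed-form solver (`rwr_direct`, `p = γ(I−(1−γ)Wᵀ)⁻¹p_0`) exists purely as
an independent cross-check of the iteration.

All L·n seeds are advanced together as columns of one matrix; because the
iteration is linear and columns are independent, freezing each column the
moment its own residual passes tolerance is exactly equivalent to running
seeds one at a time (asserted in the tests). Fusion symmetrizes the
within-layer stationary blocks: `S_fusion = Σ_j (S'_j + S'_jᵀ)/(2L)`, the
unique per-layer average consistent with the two-layer form
`(S'_1+S'_2+S'_1ᵀ+S'_2ᵀ)/4`. Cross-layer blocks `A'_jl` are retained for
diagnostics but do not enter the fusion.

## Clustering and cluster-number voting

Subtypes come from normalized spectral clustering: top-k eigenvectors of the
symmetrically normalized affinity, rows normalized to unit length, then
k-means (20 restarts, fixed seed — deterministic given the seed). The
affinity diagonal is zeroed before building the Laplacian: self-affinity
carries no between-sample information, and a unit self-loop hands every
near-isolated sample (e.g. a heavy-tailed noise outlier whose off-diagonal
affinities underflow) a normalized-affinity eigenvalue of ~1, which makes
k = 2 isolate the outlier instead of splitting the classes. Removing the
diagonal pushes those eigenvalues to ~0 and eliminated that failure mode
entirely in the Gamma-noise study.

The number of clusters is recommended by seven validity indexes —
Ratkowsky–Lance, Tau, Silhouette, C-index, SD-scat, SD-Dis,
Calinski–Harabasz, in their standard forms with their usual max/min
directions — each voting for its optimal k over a scanned range (default
2–8); the two most-voted values are reported, ties resolved toward smaller
k. Distance-based indexes use the similarity-derived distance
`d = sqrt(−log(S/max_offdiag(S)))`; the log undoes the exponential kernel's
dynamic-range compression (on a linear `1 − S/max` scale nearly every pair
sits at distance ≈ 1 and all indexes drift monotonically with k). The linear
conversion remains available via `scale="linear"`. Coordinate-based indexes
(Ratkowsky–Lance, Calinski–Harabasz, SD) use a classical-MDS embedding of
that distance (up to 10 components), computed once per table so every k is
scored in the same space.

## Evaluation

- **Dunn index**: minimum between-cluster nearest-pair distance over maximum
  within-cluster diameter, computed on any supplied distance matrix (the
  pipeline uses the log-scale similarity-derived distance). All-singleton
  partitions either raise or return `inf` via a flag.
- **NMI**: mutual information normalized by the arithmetic mean of the label
  entropies (the `sqrt` variant is available; the choice affects only the
  third decimal in practice).
- **Log-rank**: standard multi-group chi-square with tie-corrected variance,
  via lifelines; significance threshold 0.05.
- **Feature ranking**: each feature, alone, is turned into a 1-D similarity
  network, spectral-clustered at the reference k, and scored by NMI against
  the reference subtypes; features are ranked descending. Constant features
  are skipped (or scored 0 via a flag).

## Synthetic benchmarks

Two generators make the full pipeline testable without external data.

**Two-cluster noise study.** 200 two-dimensional samples, 100 per class,
uniform in axis-aligned boxes of half-width `separation/4` around centers
`separation` apart (strict linear margin, so the noise-free base is exactly
linearly separable). Two views corrupt the same base: additive Gaussian
noise (mean 0, sd 1.5) and additive Gamma noise (shape 3, rate 1, added
un-centered — the mean-3 offset is a location shift that leaves pairwise
distances essentially untouched). The default `separation = 4.6` was
calibrated once so that single-view clustering is imperfect but well above
chance and the fused network recovers more: measured mean NMIs over 12
seeds were 0.625 (Gaussian view), 0.578 (Gamma view), 0.752 (fused), the
qualitative regime the method is known for. Note the per-replicate numbers
are noisy (±0.1 is common), so single-run values should not be
over-interpreted.

**Multi-view benchmark.** 100 samples in 5 shared clusters observed in
three views of dimensionality 367/131/160. Each view places cluster
centroids by Gaussian mean shifts of per-coordinate scale
`signal = (0.15, 0.28, 0.35)` on top of unit within-cluster noise, making
the views individually weak/medium/strong (measured single-view NMIs ≈
0.12/0.27/0.54 over 8 seeds; fused ≈ 0.74, exceeding every view in 8/8
seeds). This generator reproduces the *shape* of an interrelated
multi-omics simulation — shared membership, staggered per-view signal — not
any real data set's covariance structure: features are independent within a
view, noise is Gaussian and homoscedastic, and there is no cross-view
feature correlation. Passing tests therefore demonstrate the fusion
mechanics, not performance on real omics data.

## Numerical choices and edge cases

- Neighbor and similarity ties break by sample index (stable sorts), so all
  constructions are permutation-equivariant and deterministic.
- `N` and `m` are clamped to n−1 with a warning for small cohorts.
- Preprocessing: strict `>20 %` missingness thresholds, samples filtered
  before features, with the two steps repeated to a fixed point so
  filtering is idempotent; mean imputation over observed values;
  population-sd standardization (`ddof` configurable); zero-variance
  features dropped with a warning (they carry no similarity information).
- Probability vectors are validated to sum to 1 within 1e−12; transition
  rows to 1 within 1e−12; `S_fusion` is exactly symmetrized.
- k-means uses 20 restarts under a fixed base seed; results are
  reproducible bit-for-bit for a given seed.

## Known limitations

- The walk is dense (O((Ln)²) memory); cohorts beyond a few thousand
  samples would need a sparse or truncated solver, which is out of scope.
- The validity-index vote inherits the biases of its constituent indexes;
  Ratkowsky–Lance in particular favors small k on spectral embeddings.
- Survival evaluation is a single log-rank p-value; no hazard modeling.
- Feature ranking refits one network per feature and scales linearly in the
  total feature count.
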