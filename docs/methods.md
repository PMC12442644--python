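# Methods

## Problem setting and model

Spot-based spatial transcriptomics measures expression at capture spots on
a hexagonal lattice; the tissue between spots is unmeasured and each spot
aggregates several cells. The package identifies spatial domains by (i)
densifying the lattice with interpolated pseudo-spots at the centroids of
triangular gap regions, (ii) building a spatial K-nearest-neighbor graph
whose edges are weighted by cell-type compositional similarity, and (iii)
learning node embeddings with a graph-convolutional autoencoder trained
jointly on reconstruction and a contrastive objective, followed by
model-based clustering of the embeddings.

The method assumes the slide approximates a regular lattice (gap
enumeration warns when >20% of nearest-neighbor distances deviate >25%
from the modal pitch), that expression varies smoothly enough in space for
kernel interpolation to be meaningful, and that per-spot cell-type
composition carries domain signal.

### Gap enumeration

Triangular gap regions are found by Delaunay triangulation of spot
centers, keeping triangles whose longest edge is at most `pitch_factor`
(default 1.2) times the modal nearest-neighbor distance. On an ideal
hexagonal lattice this equals the exhaustive enumeration of all triples of
mutually adjacent spots (asserted against a brute-force oracle in the
tests) while remaining robust to missing spots at tissue boundaries.
Incomplete boundary triangles are simply not produced; degenerate
(collinear) triangles are skipped with a warning. Spots flagged
`in_tissue = 0` are dropped at read time.

### Interpolation

Two modes share the Cauchy kernel `k_θ(x_i, x_j) = 1/(1 + ‖x_i − x_j‖²/θ)`:

* **kernel** (default): the value at a gap centroid is the convex
  combination of its 6 nearest spots' preprocessed expression rows with
  normalized kernel weights. Convexity guarantees interpolated values stay
  within the neighborhood's range.
* **gp**: per-dimension Gaussian-process regression (zero-mean prior, the
  same kernel) in a 20-component PCA latent space, mapped back linearly.
  The posterior mean is `k*ᵀ (K + jitter·I)⁻¹ Z` and the variance
  `k(x,x) − k*ᵀ (K + jitter·I)⁻¹ k*`, floored at 0. Singular systems are
  retried with a jitter ladder (1e-8, 1e-6, 1e-4) before erroring.

The default `θ = (modal nearest-neighbor distance)²` makes the kernel
value between adjacent spots exactly 0.5; `fit_theta` can instead select θ
from a grid by leave-one-out interpolation error (ties go to the smallest
candidate). Interpolation operates on preprocessed (log-normalized,
scaled) expression because every downstream stage consumes that space; the
kernel mode is the default since it needs no matrix inversion at slide
scale. θ and the refinement radius are in the source coordinate units —
coordinates are never rescaled.

### Preprocessing

Library-size normalization to the slide's median library size, `log1p`,
selection of the top 3000 highly variable genes by variance of the
log-normalized values, then per-gene scaling to zero mean and unit
variance (sample variance, ddof 1). Zero-variance genes are dropped before
scaling. HVGs are selected before scaling so that scaling cannot equalize
the variances the selection ranks on. Single-cell references pass through
the identical routine. An all-zero spot (library size 0) is a hard error
naming the spot.

### Cell-type compositions

External deconvolution results are accepted as CSV (rows renormalized when
within 1% of summing to 1, rejected otherwise). The built-in baseline is
per-spot non-negative least squares against per-type mean expression
signatures, normalized to the simplex; an all-zero solution falls back to
uniform. When an external table covers only measured spots, pseudo-spots
receive kernel-weighted averages of their neighbors' compositions (convex,
so rows stay on the simplex). NNLS was chosen as the baseline because it
is deterministic, dependency-free and sufficient to carry composition
signal into the graph; it is not intended to compete with dedicated
deconvolution tools, which can be plugged in via the CSV interface.

### Weighted graph

The KNN digraph (K = 4) on spot coordinates is symmetrized
(`min(A + Aᵀ, 1)`); distances are computed exactly in row chunks with ties
broken by index, so graph construction is deterministic. Edge weights are
`γ + (1 − γ)·S_ij` with γ = 0.2 and `S_ij = 1/(1 + d)` where `d` is the
base-2 Jensen–Shannon divergence of the two composition vectors (bounded
in [0, 1]; zero components handled by the `0·log 0 = 0` convention).
Cosine and Pearson similarities are offered as alternatives; because the
score transform expects a divergence, they are mapped to `d = 1 − sim` by
default — feeding the raw similarity through `1/(1 + sim)` would *penalize*
similar spots. The literal transform remains available behind a flag for
comparison.

### Representation learner

Encoder: one GCN layer `Z = relu(Ã X W_e + b_e)` to 64 dimensions;
decoder: one symmetric GCN layer back to gene space with identity
activation. Ã is the symmetrically normalized adjacency
`D^(−1/2)(A + I)D^(−1/2)`; self-loops are added by default so each node
retains its own signal during convolution (the paper-literal formula
without self-loops is available behind a flag). The discriminator is
bilinear, `Φ(z, g) = sigmoid(zᵀ B g)` — the minimal two-argument form of a
`R^d × R^d → R` scorer; context vectors are sigmoids of the row-normalized
weighted mean of neighbor embeddings (self excluded; isolated nodes get
sigmoid(0) = 0.5).

The loss is `λ₁ L_recon + λ₂ (L_SCL + L_SCL′)` with λ₁ = 10, λ₂ = 1.
`L_recon` is the summed squared reconstruction error. `L_SCL` contrasts
(z_i, g_i) against (z′_i, g_i) where Z′ comes from a corruption that
row-permutes the feature matrix each epoch while keeping the topology (and
edge weights) fixed; `L_SCL′` mirrors the roles on the corrupted graph's
contexts. Both are computed from logits via softplus, equivalent to binary
cross-entropy with probabilities clamped away from {0, 1}.

Training is plain NumPy: hand-derived analytic gradients (validated
against central finite differences to 1e-4 in the tests) and an Adam
optimizer (lr 1e-3, no weight decay, 600 epochs by default). Final
embeddings are post-activation encoder outputs recomputed with the final
parameters. Everything is a deterministic function of the configured seed.
One full-graph pass is dense in the feature dimension and sparse in the
adjacency, so slides up to ~10⁴ nodes train comfortably on one CPU;
mini-batching is deliberately out of scope.

### Clustering and refinement

Embeddings are reduced to 20 principal components (deterministic sign
convention: the largest-magnitude loading of each component is positive)
and clustered with a Gaussian mixture sharing one full covariance across
components — the 'EEE' parameterization of model-based clustering —
initialized from k-means, best of 5 starts, deterministic per seed. The
alternative is Leiden/Louvain on an unweighted symmetrized 50-NN graph of
the embeddings, scanning resolutions 0.10–3.00 in steps of 0.01 and
returning the first resolution that yields the target cluster count (else
the closest count, ties to the lowest resolution).

Refinement, when requested, is one synchronous majority-vote pass: each
spot takes the modal label within the given radius (default 50 coordinate
units, self included), computed entirely from pre-pass labels; ties keep
the current label. Interpolated pseudo-spots are labeled during clustering
but excluded from reported labels and from all evaluation.

### Metrics

ARI is computed from the contingency table with exact integer binomial
coefficients (no overflow at any n); NMI uses natural-log entropies with
the conventions NMI = 1 when both partitions are single-cluster and 0 when
exactly one is (continuity with the independence limit). Both agree with
widely used reference implementations to 1e-9 on random fixtures (tested).
Per-domain Jaccard reports, for each true domain, the best overlap with
any predicted cluster.

## Synthetic data: what it does and does not emulate

The generator produces a rows × cols honeycomb lattice (pitch 100 units,
odd rows offset by half a pitch), contiguous domains (horizontal bands by
default; rectangular blocks and Voronoi cells as alternatives),
expression as `round(exp(μ_domain + N(0, noise_sd)))` where each domain
elevates a disjoint block of ~n_genes/n_domains marker genes by
`expr_effect · noise_sd` in log space, and per-spot compositions drawn
from domain-specific Dirichlets (concentration 20 on a domain's dominant
cell types, 1 elsewhere). A matching single-cell reference draws
`cells_per_type` cells around per-type signatures consistent with the
domain programs.

Defaults (20×20 spots, 200 genes, 4 domains, 8 cell types,
`expr_effect = 3`, `noise_sd = 1`, Dirichlet 20/1) define the reference
conditions used by the end-to-end tests and the acceptance script; they
were chosen once as a clearly-separable but noisy regime a practitioner
would call realistic for a layered tissue.

The generator targets log-space structure directly rather than explicit
negative-binomial counts, has no histology, no platform artifacts (spot
bleed, mis-registration), no dropout structure beyond rounding, and
markers are disjoint across domains. Passing tests therefore demonstrate
the pipeline's mechanics and determinism, not performance on real tissue:
on these conditions the domains are fully recoverable (ARI = 1), so the
fixture cannot rank the contribution of individual components — disabling
the reconstruction loss or adding 20% composition noise leaves accuracy
saturated, which is informative about robustness but not about ablation
orderings observed on real, harder slides.

## Numerical choices

* Probabilities in the contrastive losses and the discriminator are
  clamped at 1e-7; loss evaluation goes through softplus on logits.
* GP solves use Cholesky factorization with the jitter ladder above.
* KNN ties are broken by spot index (stable argsort); duplicate
  coordinates warn.
* Dirichlet rows, NNLS outputs and perturbed compositions are explicitly
  renormalized so simplex invariants hold to 1e-9.
* Composition-noise experiments multiply entries by `1 + m·U(−1, 1)`
  (relative noise) and renormalize.
* The resolution search evaluates Leiden with 2 iterations and a fixed
  seed; Louvain seeds igraph's global RNG per call.

## Known limitations

* Square-grid slides are accepted but gap triangles become halves of grid
  cells; behavior there is documented, not validated.
* The NNLS baseline ignores platform effects between reference and slide.
* The refinement radius and θ are unit-dependent; inputs with pixel
  coordinates need a radius on that scale.
* Full-graph training stores dense node-feature intermediates; very large
  slides (≫10⁴ nodes) would need mini-batching, which is out of scope.
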