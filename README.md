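# sgcd

Spatial-domain identification for spot-based spatial transcriptomics.

Spot-based platforms (10X Visium and kin) measure whole transcriptomes at
capture spots laid out on a hexagonal lattice with a ~100 µm pitch. Because
each 55 µm spot covers only a fraction of the tissue, roughly 70% of the
slide area is never measured, and each spot mixes transcripts from several
cells. `sgcd` segments such slides into spatial domains — contiguous tissue
regions with a coherent expression and cell-type profile (e.g. cortical
layers, tumor vs. stroma) — by combining three ideas:

1. **Gap interpolation.** Every triangle of three mutually adjacent spots
   encloses an unmeasured gap region. Expression at the triangle centroid is
   estimated by Cauchy-kernel weighting of neighboring spots,

   `k_θ(x_i, x_j) = 1 / (1 + ‖x_i − x_j‖² / θ)`,
   `α_i = k_θ(x_new, x_i) / Σ_j k_θ(x_new, x_j)`,

   or, alternatively, by Gaussian-process regression with the same kernel
   (posterior mean `k*ᵀ K⁻¹ Z`, variance `k(x,x) − k*ᵀ K⁻¹ k*`) in a PCA
   latent space. Interpolated pseudo-spots join the measured spots as
   first-class graph nodes.

2. **Cell-type-aware graph weighting.** A K-nearest-neighbor graph (K = 4)
   on spot coordinates is weighted by the similarity of per-spot cell-type
   compositions (obtained from an external deconvolution tool or the
   built-in NNLS baseline): with Jensen–Shannon divergence `JSD(P‖Q)` the
   edge score is `S_ij = 1 / (1 + JSD)` and the weight

   `w_ij = γ + (1 − γ) · S_ij`,   γ = 0.2,

   so spatial neighbors never drop below the baseline weight γ even when
   their compositions are disjoint.

3. **Graph contrastive representation learning.** A one-layer GCN encoder
   `Z = σ(Ã X W_e + b_e)` with symmetric decoder is trained by

   `L = λ₁ L_recon + λ₂ (L_SCL + L_SCL′)`,   λ₁ = 10, λ₂ = 1,

   where `L_recon = Σ_i ‖x_i − h_i‖²` and the two contrastive terms are
   binary cross-entropies of a bilinear discriminator `Φ(z, g) =
   sigmoid(zᵀ B g)` separating each node's embedding from its local context
   vector `g_i` against a corrupted graph whose features are row-permuted
   every epoch (topology unchanged).

Embeddings are reduced to 20 principal components and clustered with a
tied-covariance Gaussian mixture (the mclust-'EEE' model) when the number
of domains is known, or by Leiden/Louvain with an adaptive resolution
search (0.10–3.00, step 0.01, 50-NN graph) otherwise; an optional spatial
refinement pass reassigns each spot to the modal label within a radius.
Results are scored by ARI, NMI and per-domain Jaccard overlap.

A synthetic-slide generator (hexagonal lattice, banded/blocky/Voronoi
domains, log-space marker programs, domain-specific Dirichlet cell-type
compositions) makes every stage testable without downloading data.

## Worked example

```python
import sgcd

sim = sgcd.simulate_slide(sgcd.SimulationConfig(rows=12, cols=12,
                                                n_genes=120, seed=0))
config = sgcd.RunConfig(n_clusters=4, epochs=150, seed=0)
result = sgcd.run_pipeline(sim.table, config, proportions=sim.proportions)

print(f"spots: {sim.table.n_spots}, nodes after interpolation: {result.table.n_spots}")
print(f"edges: {len(result.graph.weights)}, weight range: "
      f"[{result.graph.weights.min():.3f}, {result.graph.weights.max():.3f}]")
print(f"ARI = {result.metrics['ari']:.3f}, NMI = {result.metrics['nmi']:.3f}")
```

prints

```
spots: 144, nodes after interpolation: 386
edges: 982, weight range: [0.656, 1.000]
ARI = 1.000, NMI = 1.000
```

144 lattice spots gain 242 interpolated pseudo-spots (two gap triangles per
lattice cell), the weighted graph keeps every edge above γ = 0.2 — here the
domain structure is strong, so weights stay above 0.65 — and the recovered
domains match the generating four bands exactly (ARI/NMI = 1 over the 144
measured spots; pseudo-spots are never evaluated).

The same pipeline is available from the shell:

```bash
sgcd simulate --rows 12 --cols 12 --n-genes 120 --seed 0 --out sim/
sgcd run --in sim/slide.h5ad --props sim/proportions.csv \
         --truth sim/truth.csv --n-clusters 4 --seed 0 --out run/
sgcd eval --pred run/labels.csv --truth sim/truth.csv
```

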