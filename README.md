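# chromalink

High-resolution chromatin contact maps (Hi-C) exist for only a handful of
cell types, yet most disease-associated non-coding variants act through
cell-type-specific long-range regulation.  `chromalink` implements an
end-to-end computational route from 1D epigenomic signals to
variant-to-subnetwork interpretation:

1. **Contact-count prediction.**  A chromosome is tiled into non-overlapping
   1 Mb segments and a separate random-forest regressor is trained per
   segment on 5 kb bin pairs, using a 31-dimensional discretized feature
   vector per pair (10 per-bin features for each anchor — seven
   histone/accessibility signals k-means-discretized into 20 levels plus
   three accessible-motif counts — the window between the anchors, and the
   genomic distance).  Models trained in one cell type predict counts in
   another; pairs spanning two segments average the two models.
2. **Loop calling.**  Significant interactions are called per distance
   stratum *d* with a uniform-background binomial test,
   P(K ≥ k | n_d, m_d) with m_d = 1/#candidate pairs at distance *d*,
   Benjamini–Hochberg corrected (q < 0.05).
3. **TADs and evaluation.**  Directionality-Index domain calling
   (DI = sign(B−A)·((A−E)²/E + (B−E)²/E) over a 2 Mb window), TAD-set
   Jaccard similarity, distance-stratified Pearson-correlation AUC, fold
   enrichment (q/k)/(m/S), and eQTL precision/recall with a nearest-gene
   baseline.
4. **Variant linking.**  Non-coding SNPs (with LD proxies) are mapped to
   genes whose promoter window (TSS ± 2500 bp) loops to the SNP's bin; a
   gene's score is the mean −log₁₀(q) of its SNP interactions.
5. **Network diffusion.**  Over merged PPI + proximal + distal TF–gene
   networks, scores are diffused with the regularized Laplacian kernel
   K_L = (I + λL)⁻¹ (λ = 1 by LOO cross-validation), edges reweighted with
   the insulated heat kernel K_H = β(I − (1−β)W)⁻¹ (β = 0.3), and the
   selected submatrix (direct hits ∪ top 1% of diffused scores) converted to
   a diffusion-state-distance matrix and Gaussian similarity
   S = exp(−P²/2σ_P²).
6. **Multi-task clustering.**  Tree-guided spectral clustering on the
   regularized Laplacian L_τ = I − D_τ^{−1/2} A D_τ^{−1/2} (D_τ = D + μ_D)
   with cluster identities matched across cell types, modularity-based k
   selection, transitioning-gene-set detection, and hypergeometric/NMF
   enrichment summaries.

A synthetic-data module generates every input with recorded ground truth
(block-structured contact matrices with power-law decay, signal panels whose
features determine the counts, multi-cell-type stochastic-block-model gene
networks on a known cell-type tree, SNP studies with planted links), so
every stage is testable end to end.

## Worked example

```python
import chromalink as cl
from chromalink import fixtures

spec = cl.SyntheticSpec(n_bins=400, n_tads=4, noise_sd=0.0, seed=2)
data = fixtures.synth_regression_dataset(spec)

ens = cl.train_local(data["train_table"], params=cl.ForestParams(n_trees=40), seed=0)
pred = cl.predict_counts(ens, data["test_table"], n_bins=spec.n_bins)
curve, auc = cl.stratified_correlation_auc(pred, data["test_matrix"])
print(f"held-out distance-stratified AUC: {auc:.3f} over {len(curve)} strata")

di = cl.directionality_index(data["test_matrix"])
tads = cl.call_tads(di, chrom=spec.chrom)
print("recovered TAD boundaries:", cl.tad_boundaries(tads))
print("planted boundaries:      ", data["boundaries"])
```

prints

```
held-out distance-stratified AUC: 0.997 over 99 strata
recovered TAD boundaries: [100, 200, 300]
planted boundaries:       [100, 200, 300]
```

i.e. on a noise-free 2 Mb synthetic chromosome the cross-cell-type forest
recovers the counts almost perfectly (Pearson r ≈ 1 in every informative
distance stratum) and the DI caller recovers the three planted domain
boundaries exactly.

A command-line interface mirrors the library
(`chromalink simulate|features|train|predict|callloops|calltads|evaluate|linksnps|buildnet|diffuse|cluster`);
run `chromalink --help`.

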