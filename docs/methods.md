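# Methods

This note documents the models implemented in `chromalink`, the parameters
that matter, the synthetic data the tests run on, and the design choices
made where the design was genuinely open.

## Coordinates and containers

All coordinates are 0-based half-open; the genomic unit is a 5 kb bin
(`index = floor(position/5000)`).  Contact matrices are intra-chromosomal,
upper-triangular, and restricted to pair spans of 1–200 bins (5 kb–1 Mb);
counts are stored as reals because normalized and predicted counts are
non-integer.  Strand is ignored throughout.

## Pair features and discretization

Each bin carries 10 features: seven signal tracks (DNase, H3K27ac, H3K27me3,
H3K36me3, H3K4me1, H3K4me3, H3K9me3), depth-normalized (counts per million)
and replicate-collapsed by the median, each discretized into 20 levels by
1-D k-means; and three accessible-motif count tracks (CTCF, RAD21, TBP;
hits kept at purity > 0.50, assigned to the bin of their start).  A pair
(i, j) is the concatenation of region-i features, window features over bins
i+1..j−1, region-j features, and the raw distance in bp — 31 columns.

Open choices resolved here:

* *Level matching across cell types* — k-means centers are fitted once on
  the training cell type and applied unchanged everywhere; levels are
  ordered by center value.  Refitting per cell type would let levels drift
  and break comparability.
* *Window over signals* — the mean of the discrete levels (reals allowed),
  not re-discretized.  The alternative (average raw signal, then
  discretize) is available via `window_mode="raw"`.
* *Adjacent pairs* (no intervening bin) use the mean of the two anchor
  values, the continuous limit of the window definition.
* *Motif windows* use total count divided by the number of intervening
  bins (a density, not a level mean).

## Local contact-count regression

Segments are fixed 1 Mb tiles.  A pair trains every segment containing one
of its anchors (one or two); prediction averages the (one or two) segment
models and clamps negatives at 0.  Forest hyperparameters are not dictated
by the method: defaults are 100 trees, ⌈p/3⌉ features per split, unlimited
depth, all configurable and recorded in model metadata.  A missing segment
model falls back to the nearest trained segment with a warning.  Baselines:
*transfer count* (training counts copied verbatim) and a single
whole-chromosome forest.

## Binomial loop calling

Counts are rounded half-to-even (the test needs integers; rounding
approximately preserves totals).  Per stratum *d*, the candidate universe is
*all* bin pairs at that distance, m_d = 1/(n_bins − d), n_d = total rounded
counts, and p = P(K ≥ k | n_d, m_d).  BH runs within each stratum by
default, with the full candidate universe as the test count (zero-count
pairs enter at p = 1, which cannot change other pairs' step-up q);
`--global-fdr` pools across strata.  Because correction is per stratum, the
FDR guarantee is per distance family — the null simulation in the test
suite measures exactly that quantity.

## TAD calling

DI uses a 2 Mb window, truncated at chromosome edges; A = B or E = 0 gives
DI = 0.  Segmentation is a deterministic sign-run rule: a boundary at the
start of a ≥3-bin positive run that follows a ≥3-bin negative run, domains
spanning consecutive boundaries, minimum 3 bins.  The HMM of the original
DI formulation is deliberately out of scope: the Jaccard comparison between
two matrices is insensitive to the segmentation variant as long as both
matrices are segmented the same way.  TAD-set similarity is the symmetrized
mean best-match bp-level Jaccard; two empty sets score 1, empty vs
non-empty 0.

## Evaluation metrics

Distance-stratified Pearson r is computed over all candidate pairs per
stratum (missing entries 0); strata with < 3 pairs or (numerically) zero
variance are skipped; the AUC is the mean of r over retained strata (the
trapezoid rule on a uniform grid).  Fold enrichment is (q/k)/(m/S),
undefined (NaN) when k or m is 0.  eQTL precision/recall is stratified in
100 kb distance bins up to 1 Mb.  The expression comparison uses
log(RPKM + 0.1) — the pseudocount shields zeros — and a two-sample t-test.

## SNP-to-gene linking and node scores

A gene claims every bin overlapping its TSS ± 2500 bp window; a SNP sits in
the bin of its position; a link is emitted when (snp_bin, gene_bin) is a
significant loop.  Each distinct (SNP, gene) pair counts once (keeping its
smallest q) even if several loops support it.  Scores use −log base 10
(conventional for q-values; the base only rescales diffusion inputs
uniformly), with q clamped at 1e−300.  LD expansion is an input (lead →
proxy TSV at R² ≥ 0.8); proxies are ordinary SNPs downstream.

## Networks and the cell-type tree

PPI edges kept at confidence > 0.95; proximal TF–gene edges need a motif
hit with purity > 0.9 inside the promoter window; distal edges need a
significant loop joining the promoter bin to a motif-carrying bin (a motif
sharing the promoter anchor is proximal territory, not distal).  The top 5%
purity filter is applied separately within the proximal and distal classes;
ties at the cutoff are all retained (may slightly exceed 5%) rather than
dropped arbitrarily.  Merged edges are unweighted; the graph is undirected —
the symmetric kernels below presuppose it.  Cell-type trees are UPGMA on
Euclidean distances, either of promoter H3K4me3 profiles or of
loop-overlap F-score profiles; tree agreement is scored by the
Fowlkes–Mallows index with a leaf-permutation null.

## Two-step diffusion

Node diffusion: V = (I + λL)⁻¹Q with L = I − D^{−1/2}AD^{−1/2}; λ from
{0.1, 0.5, 1, 5, 10} by leave-one-out AUROC over direct hits, ties to the
smaller λ, default 1.  Edge diffusion: K_H = β(I − (1−β)W)⁻¹ with
W = AD⁻¹ and β = 0.3; H = K_H·diag(V).  Degree-0 nodes get a zero
D^{−1/2} entry and a self-retaining transition column, keeping both kernels
well defined.  All kernels go through linear solves (Cholesky where
symmetric), never explicit inverses.  The DSD matrix is the L1 distance
between rows of H restricted to the selected nodes (direct hits ∪ top 1% of
V, ties included); full-row diffusion states are available via
`dsd_rows="all"`.  σ_P is the population standard deviation of all entries
of P; S = exp(−P²/2σ_P²), with S = 1 everywhere in the degenerate σ_P = 0
case.

## Multi-task clustering

Spectral embedding uses L_τ = I − D_τ^{−1/2}AD_τ^{−1/2} with
D_τ = D + mean(D); rows of the k bottom eigenvectors are unit-normalized
(zero rows left zero).  Cross-cell-type correspondence is a tree-guided
warm-start scheme: embeddings are aligned to a reference (from the
leaf-averaged similarity) by orthogonal Procrustes; k-means runs root →
leaves, the root seeded by k-means++ on the reference (50 restarts), each
child warm-started from its parent's centroids (single init, preserving
correspondence).  This is a variant reconstruction of tree-guided
multi-task spectral clustering from its two contracts — per-cell-type
spectral clustering on L_τ and tree-guided cluster correspondence — since
the original optimization is not restated here.  k is selected from
{6, 7, 8, 9} by average modularity subject to a minimum cluster size of 5.

Transitioning gene sets: Hamming-fraction distance on label vectors (so the
0.1 cut height means "≤10% of cell types disagree" within a set),
average linkage with optimal leaf ordering, sets < 5 genes dropped; a set is
conserved iff all members share a single label in every cell type.
Enrichment is an upper-tail hypergeometric test per term with BH across
terms (q < 0.05); the term × gene-list −log q matrix is summarized by
rank-7 NMF (multiplicative updates, nndsvda initialization, iteration cap
5000 at tolerance 1e−6 — the cap exists because multiplicative updates
converge slowly near exact low-rank solutions), reporting explained
variance EV = 1 − var(x − x̂)/var(x) and the top 10 terms / top 5 columns
per factor.

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` defaults define the study conditions: a 3 Mb chromosome
(600 bins, the regression tests use the 400-bin minimum) with equal-width
TADs, counts = base·d^(−α)·(1 + boost·same_block)·exp(ε) with α = 1,
base = 100, boost = 1 and log-normal noise (multiplicative noise keeps
counts positive and heavy-tailed, as real Hi-C counts are); 3 cell types;
300 genes in 6 stochastic-block-model modules (p_within = 0.30,
p_between = 0.02) on a UPGMA caterpillar tree.  The boundary-marker motif
tracks (CTCF/RAD21-like) peak exactly at planted boundaries, so the
noise-free counts are an exact function of (distance, motif window/anchor)
— the recorded generating function.  Nuisance-track *shapes* are shared
between the train and test cell types while noise realizations differ;
this isolates cross-cell-type transfer of the count-feature relationship
from assay-level divergence.  For the local-vs-global comparison,
`segment_params` makes base and boost differ per 1 Mb segment while the
features carry no positional information, so only segment-local models can
represent the law.

The planted transitioning event moves a **minority** of module 0 (20 of 50
genes) into module 1 inside the designated subtree.  A full module merge
would change the cluster count in part of the tree (making ground-truth ARI
ill-posed), and a symmetric half-swap leaves the new communities 50/50
mixtures of the old ones, making cross-cell-type label correspondence
fundamentally ambiguous; the minority move keeps every cluster anchored by
a majority of its original members.

What passing these tests does **not** show about real data: the generators
have exact block TADs, a single known count law, Bernoulli-independent
network edges and promoter windows aligned to bin centers; real signal
tracks are noisier, TAD boundaries fuzzier, networks scale-free-ish, and
imputation/normalization artifacts are absent entirely.

## Problem sizes and numerics

Test and acceptance runs use a 400-bin chromosome (≈60 k pairs), 40-tree
forests for noise-free recovery and 15-tree depth-14 forests on 15 k-pair
subsamples for the 10-seed local-vs-global comparison; 200 replicates of a
150-bin universe for the null-FDR simulation; 200-node graphs for kernel
oracles; 10 seeds of the 300-gene, 3-cell-type network fixture for
clustering recovery.  These sizes were chosen so the full statistical
structure is present at seconds-to-minutes scale.  Numerical conventions:
binomial p-values via the survival function (k = 0 → p = 1); counts
rounded half-to-even; correlation strata with relative variance below
1e−12 treated as constant; eigen-decompositions via symmetric solvers;
kernel systems solved, not inverted.

## Known limitations

No HMM-based DI segmentation or nested TADs; no spline-null or local-model
loop callers; no ICE/SQRTVC normalization (normalized counts are inputs);
the multi-task clustering is a documented variant, not a re-derivation of
the published optimization; Newick round-trips reconstruct the linkage via
UPGMA on path distances and are exact only for ultrametric trees; LD
expansion and motif scanning are consumed as inputs, never computed.
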