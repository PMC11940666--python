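# Methods

`hicenhance` enhances low-depth Hi-C contact maps: given a sparsely
sequenced (bulk) or ultra-sparse (single-cell) contact matrix, it
predicts the matrix that deeper sequencing of the same sample would
have produced. This note records the model, the preprocessing and
evaluation conventions, the synthetic data generator used for the
bundled benchmarks, and the numerical choices behind the
implementation.

## 1. Problem setting and data model

A contact map is a symmetric non-negative matrix whose entry (i, j)
counts ligation events between genomic bins i and j of one chromosome.
`ContactMap` (in `hicenhance.io_formats`) carries the matrix together
with its chromosome name, bin size and a processing `state` tag —
`raw_counts`, `balanced` or `scaled01` — so that every downstream
function can check it receives data at the stage it expects. Maps
round-trip through two text-friendly containers: a COO TSV
(`bin_i  bin_j  count`, upper triangle) and a NumPy `.npz` archive.

Preprocessing follows the standard Hi-C sequence:

1. **Balancing.** `kr_balance` performs Knight–Ruiz matrix balancing
   via Sinkhorn iteration, returning a matrix whose non-empty rows all
   sum to the same mass, plus the bin-wise scaling vector. Empty rows
   are masked and reported rather than inflated.
2. **Scaling.** `normalize01` divides by the 99.9th-percentile value
   and clips to [0, 1], which protects the network from the few
   extreme near-diagonal entries.
3. **Tiling.** `split_blocks` cuts a map into H×H tiles (default
   H = 40) on a regular grid, optionally with a stride smaller than H
   (overlapping tiles) and optionally restricted to tiles near the
   diagonal. `merge_blocks` inverts the tiling exactly and
   re-symmetrizes.

For a (low-depth, high-depth) training pair, `scale_pair` balances both
maps independently and divides *both* by the high-depth map's
percentile cap. Balancing equalizes row sums, so after this joint
scaling the depth difference appears where it belongs — as sparsity and
noise in the low map — rather than as a brightness offset that the
network would have to memorize.

Low-depth bulk maps are produced from deep maps by `downsample`
(binomial thinning of each upper-triangle count, preserving symmetry
and expected totals). Single-cell maps go through `cell_qc` (minimum
total contacts, minimum non-empty bins, maximum fraction of mass on the
diagonal) and `build_pseudobulk`, which sums each cell with its k most
similar kept cells (Pearson similarity of flattened upper triangles,
ties broken by cell identifier) to form a per-cell enhancement target.

## 2. Synthetic data generator

Real Hi-C experiments have no observable ground truth at high depth, so
the bundled benchmarks use a generator whose truth is known by
construction (`hicenhance.synthetic`):

- an intensity matrix with power-law distance decay
  `(1 + |i − j|)^(−α)` (default α = 1),
- multiplicative TAD blocks (`(start, end, boost)` triples) and
  optional Gaussian loop peaks,
- Poisson sampling of the upper triangle at a target total depth for
  bulk maps, and multinomial sampling of 1 000–5 000 contacts per cell
  for single-cell populations (`CellPopulationSpec`, several cell
  types distinguished by their TAD layouts, with a configurable
  fraction of deliberately corrupted cells for QC testing).

The noiseless intensity matrix (`intensity_matrix` / `ground_truth`) is
the referee for benchmark scoring: it is what an infinitely deep
experiment on the same chromosome would converge to, passed through the
same balancing and scaling pipeline as the predictions.

## 3. Model

`HiCEnhancer` (`hicenhance.model`) maps a (B, 1, H, H) batch of scaled
tiles to same-shape enhanced tiles. Default configuration: C = 32
channels, 3 hybrid refinement modules, 8 attention heads, 5 token
segments, pixel-shuffle scale r = 1. Components:

- **PCFE** (prior convolutional feature extractor): two 3×3
  convolutions lifting 1 → C channels, output `F_base`.
- **CCE** (cascaded CNN encoder): a chain of **HRMs** (hybrid
  refinement modules). Each HRM runs CRM → DREM, then splits the
  signal into a low-frequency path (2×2 average-pool, five
  applications of a single weight-shared DREM, bilinear upsample) and
  a high-frequency path (input minus its smoothed self, one DREM),
  concatenates the two, reduces 2C → C by a 1×1 convolution, applies
  DREM → CRM and adds the module input. A **CRM** is three stages of
  residual block → concatenation with the stage input → 1×1
  reduction; a **DREM** is two residual units with learnable scalar
  gates `w_id·x + w_res·unit(x)` (both initialized to 1), concatenated
  and fused by 1×1 and 3×3 convolutions. The outputs of all HRMs are
  concatenated into `F_local`.
- **TGFF** (transformer global feature fusion): one pre-norm
  transformer block over the HW token sequence — efficient multi-head
  self-attention (EMHSA) that splits the tokens into s segments and
  attends within each segment (cost HW²/s instead of (HW)²), then a
  SwiGLU-gated MLP, each with a residual connection.
- **HRR** (high-resolution reconstruction): `I_HR =
  conv(shuffle(conv(F_global))) + conv(shuffle(F_base))`, where
  `shuffle` is pixel-shuffle (identity at r = 1) and the final
  convolutions map to 1 channel. There is deliberately no global
  input→output residual; the network reconstructs the map from
  features (see §7 for a consequence).

Inference output is clamped to [0, 1]; training uses the raw output so
gradients flow everywhere.

## 4. Loss

The training loss is a weighted composite
`L = MSE + L1 + λ1·L_FC + λ2·L_TV` with λ1 = 0.01, λ2 = 1e-5:

- pixel MSE and L1 between output O and reference R;
- **feature-consistency** `L_FC`: MSE between feature maps of O and R
  under a frozen convolutional extractor. Offline, the extractor is a
  fixed randomly initialized CNN (features are frozen either way, so
  matching them still enforces multi-scale structural agreement);
- **total-variation** `L_TV`: sum of mean absolute horizontal and
  vertical first differences of O, raised to φ = 1, as a smoothness
  prior.

## 5. Training

`hicenhance.training.train` runs Adam with the stepped schedule
`lr(e) = 2e-4 · 0.5^⌊e/5⌋`, seeded shuffling, and mini-batches of 16
tiles. When a validation pair set is given, the checkpoint with the
highest mean per-tile validation SSIM is restored at the end. A
non-finite loss aborts immediately. `enhance` applies a trained model
to a whole chromosome: tile, predict, merge, symmetrize.

## 6. Evaluation

`hicenhance.evaluation` implements the metrics from first principles:

- **SSIM** with the standard 11-tap Gaussian window (σ = 1.5) and
  constants (k₁L)², (k₂L)²; **PSNR**; **MSE**.
- **GenomeDISCO**: both maps are symmetrized and row-normalized into
  transition matrices; the score is `1 − ½‖Tₓᵗ − T_yᵗ‖₁` after scaling
  each powered matrix to unit mass (default t = 3 random-walk steps).
- **HiCRep SCC**: (2h+1)² mean-filter smoothing, per-diagonal strata,
  stratum-weighted Pearson correlation with weights
  `N_d · sd(x_d) · sd(y_d)`.
- **Clustering recovery** for single cells: log1p-transformed (raw) or
  as-is (enhanced) upper-triangle features → PCA to 40 components →
  Leiden community detection on a kNN graph → adjusted Rand index
  against the generating cell types.

Every metric is cross-checked in the test suite against an independent
brute-force implementation on small random matrices.

## 7. Numerical implementation and benchmark scales

No GPU deep-learning framework is assumed: the network, its gradients
and Adam run on a compact reverse-mode automatic-differentiation engine
in `hicenhance.nn` (NumPy throughout; convolutions via strided
shift-stacking and batched GEMM, fused scaled-dot-product attention, a
scratch-buffer pool to avoid allocator churn). Gradients of every
operation are verified against finite differences and float64 analytic
oracles; convolutions against `scipy.signal`.

The bundled end-to-end studies (`scripts/acceptance.py`) are sized to
run on a single CPU core in minutes:

- **Bulk benchmark**: one 200-bin training chromosome and one held-out
  200-bin test chromosome (α = 1, four TADs of boost 3, depth 2×10⁶),
  thinned 16-fold; reduced model (C = 16, one HRM); 289 overlapping
  40×40 tile pairs (stride 12); 10 epochs. At the bundled fixed
  seeds, enhancement raises SSIM against the noiseless ground truth by
  ≈ 0.03–0.04 over the thinned input. Training at this small scale is
  seed-sensitive: under other seeds the 10-epoch run can converge to a
  visibly worse optimum and lose that margin, so
  `scripts/acceptance.py` reports whatever its derived seeds produce
  rather than a guaranteed gain.
- **Single-cell benchmark**: 3 cell types × 50 cells at 1 000–5 000
  contacts each; QC, k = 10 pseudo-bulk targets, enhancement of every
  kept cell, then PCA/Leiden/ARI for raw versus enhanced maps.

**Known limitation.** On the bulk benchmark the enhanced maps improve
SSIM and PSNR but can score *lower* than the KR-balanced thinned input
on GenomeDISCO. The mechanism is understood: balancing equalizes row
sums and the t-step random walk averages out thinning noise, so the
thinned input's *relative* row structure is already nearly exact; the
network, lacking a global input residual (§3), slightly under-predicts
absolute intensity — most visibly on the main diagonal — and row
normalization turns that bias into off-diagonal probability mass.
SSIM, being locally mean/variance normalized, is insensitive to this
bias. Closing the gap would require longer optimization, a
diagonal-aware loss weighting, or a global skip connection, each a
departure from the model specification adopted here.
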