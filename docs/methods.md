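# Methods

## The problem

Array-based spatial transcriptomics measures a UMI count vector per capture
spot together with the spot's 2-D position in the tissue. Spatial domains —
regions such as cortical layers or tumor compartments that share an
expression program — must be recovered without supervision from data that
are high-dimensional, sparse (excess zeros from capture dropout) and
overdispersed. `spatialdg` learns a low-dimensional spot embedding that
fuses molecular similarity with spatial context and calls domains by
K-means on that embedding.

## Model

### Dual graphs

Two binary graphs over the n spots are built once, before training, and
frozen:

* **Spatial graph** A_s: spots i ≠ j are adjacent when their Euclidean
  distance is at most a radius r (inclusive). Default r = 550 in Visium
  coordinate units, which covers a spot's six immediate hexagonal
  neighbors; r = 50 suits Slide-seqV2-scale coordinates; the synthetic
  layouts use 1.2× the lattice spacing for the same first-shell coverage.
* **Feature graph** A_f: each spot is linked to its k = 15 most
  cosine-similar spots (on the preprocessed expression), ties broken by
  lower spot index, then symmetrized by union so every spot keeps between
  k and 2k neighbors.

Neither graph carries self-loops; the identity is added only inside the
symmetric normalization D̃^{-1/2}(A + I)D̃^{-1/2} used by every
convolution, which maps isolated spots to self-weight 1 and has spectral
radius ≤ 1.

### Encoder

Three two-layer GCN branches (d′ → 128 → 64, ReLU on both layers, dropout
0.1 after the first layer of each branch, train mode only) share the input
X: a spatial branch over A_s, a feature branch over A_f, and a
co-convolution branch that propagates over both graphs with a single
shared weight matrix per layer, so its gradients accumulate from both
paths. The two co-convolution outputs are averaged into the common view
H_c = (H_sc + H_fc)/2, and a consistency penalty

    L_con = || R_sc R_scᵀ − R_fc R_fcᵀ ||²_F

on the row-normalized (unit-norm, ε = 1e-12 guard) co-embeddings ties the
spot-similarity structure of the two graph views together; it is invariant
to per-row positive rescaling.

A per-spot attention softmax across the three views scores each view by a
shared attention vector applied to a tanh transform of its embedding; the
resulting convex weights combine the views, and a final bias-free 64→64
linear layer produces the fused embedding H. With identical views the
weights are exactly 1/3 each. The softmax runs across the three views per
spot (not across spots), since the coefficients serve as convex
combination weights; the attention transform, bias and scoring vector are
shared across views.

### Contrastive module

A one-hidden-layer MLP (64 → 64 → 64, ReLU) projects the attention-weighted
sum into the contrast space h_contrast used by everything below. The
global summary s is a degree-weighted mean of h_contrast with weights
w_i = 1 + deg_s(i) (the +1 keeps edgeless graphs defined), squashed by a
sigmoid so the bilinear discriminator

    D(h_i, s) = σ(h_iᵀ W s + b₀ · deg_s(i)/max deg)

stays well-scaled. The spatial bias term is realized as one learnable
scalar b₀ times the normalized spatial degree — monotone in local
connectivity at the cost of a single parameter.

**Hard negatives.** For each spot the exclusion set is itself plus its
spatial and feature neighbors; among the remaining candidates the one
with the highest cosine similarity in the current embedding is the
negative (ties to the lower index); spots with no candidates draw a
seeded uniform random partner. Negatives are re-mined every epoch from
the current embeddings; the row-blocked computation is contractually
identical to the full-matrix scan. The DGI loss is the mean binary
cross-entropy over positive (h_i, s) and negative (h_neg(i), s) pairs,
log arguments floored at 1e-12, plus an optional smoothness penalty
λ_spatial · Σ_edges ||h_i − h_j||². λ_spatial defaults to 0 because the
same attraction already enters through the spatial regularizer below;
setting it > 0 restores the literal combined form. Row-shuffle feature
corruption and Bernoulli edge dropout (p = 0.1) are available as optional
augmentation flags but default off — negatives come from hard mining, not
corruption.

### ZINB decoder

Three single-layer heads map the fused H to per-spot-per-gene parameters:
π = sigmoid(f_π(H)), μ = clamp(exp(f_μ(H)), 1e-5, 1e6),
θ = clamp(softplus(f_θ(H)), 1e-4, 1e4). The likelihood uses the
mean-dispersion NB parameterization; the zero-inflated pmf is
π·1[x=0] + (1−π)·NB(x; μ, θ), evaluated in log space through log-gamma
with probabilities floored at 1e-12. The reconstruction target is the raw
count matrix of the selected genes (a count model needs counts), while
the encoder consumes the scaled expression; no size factor enters μ —
library-size variation is handled by the input normalization only.
Dispersion is a full per-spot-per-gene matrix. Imputed ("enhanced")
expression is μ by default, optionally (1−π)·μ.

### Spatial regularizer and total objective

    L_reg = Σ_{(i,j)∈E_s} ||h_i−h_j||²/2 − λ Σ_{(i,k)∈E_neg} ||h_i−h_k||²/2

with E_neg a per-epoch uniform resample of non-neighbor pairs of the same
size as the spatial edge set and λ = 0.1. The total objective is

    L_total = α L_ZINB + β L_con + γ L_reg + δ L_DGI,
    α = 10.0, β = 0.1, γ = 0.1, δ = 0.15.

The component functions return raw sums; the trainer logs size-normalized
values (ZINB per matrix entry, consistency per Gram entry, regularizer
per positive edge, DGI already a per-spot mean) so all four components
are O(1) and the weights express a meaningful balance — with raw sums the
ZINB term over n·d′ entries would dominate by orders of magnitude. The
logged decomposition identity l_total = α·l_zinb + β·l_con + γ·l_reg +
δ·l_dgi holds at every epoch.

### Training

Full-batch (the graphs are whole-tissue objects) Adam with learning rate
1e-3 and L2 weight decay 1e-5, at most 200 epochs, gradient clipping at
global norm 5.0 (an engineering safeguard for the bilinear discriminator;
switchable). Early stopping monitors the reconstruction loss with
patience 20 and a relative min-delta of 1e-4, restoring the best-loss
weights. Glorot-uniform initialization; every randomness source (init,
dropout masks, negative-pair resampling, the hard-negative fallback)
derives from one seed, so runs are bit-reproducible on a fixed machine.

The neural components run on a compact reverse-mode automatic
differentiation engine over NumPy arrays (`spatialdg.autodiff`), covering
exactly the operator set the model needs; every operator is
gradient-checked against central finite differences in the test suite,
and value clamps carry a zero sub-gradient outside their interval so
clamp boundaries cannot produce non-finite gradients.

### Domain calling

K-means (k-means++, best of 10 seeded restarts by within-cluster sum of
squares) on the fused embeddings; K is user input, per prior biological
knowledge. An optional one-pass strict-majority smoothing over spatial
neighbors exists but is off by default so the headline output is the raw
K-means partition. Agreement with ground truth is scored by the adjusted
Rand index.

## Ablations

Four switches mirror the component analysis: `dual_graph=off` replaces
the feature graph with the spatial graph in every branch (single-view);
`dgi=off` sets δ = 0 and skips negative mining; `consistency=off` sets
β = 0; `zinb=off` sets α = 0 and substitutes a mean-squared Gaussian
reconstruction of the scaled expression (logged separately and added to
the total) so a training signal remains.

## Synthetic data

The generator emulates the structure the method assumes: spots on a
hexagonal (default), square, or uniform-random planar layout; K ≥ 2
spatially contiguous domains as parallel stripes (cortical-layer-like,
by position quantiles so domains are balanced), distance-jittered blobs,
or Voronoi cells; per-domain programs in which each domain's marker genes
have their NB mean multiplied by a fold change; lognormal per-spot
library-size factors; and ZINB counts drawn as a gamma–Poisson mixture
followed by independent Bernoulli zeroing — exact under the adopted NB
parameterization. Labels and the generative mean matrix are stored for
exact scoring. A spot that draws all zeros receives one pseudo-count in
its domain's first marker gene so preprocessing stays defined
(vanishingly rare at the default means).

The canonical benchmark (`easy_benchmark`) is 1000 hex spots, 5 stripe
domains, 200 genes with 20 markers per domain at 4-fold enrichment,
θ = 2, 30% dropout, base mean 1.0, library-size CV 0.2, lattice spacing
100 (so the spatial radius 120 covers exactly the six-neighbor shell).
At these settings roughly 59% of counts are zero. What the generator does
**not** emulate: gene–gene correlation beyond domain programs, spatially
smooth within-domain gradients, histology, platform-specific artifacts,
or batch effects — so passing tests demonstrate correct mechanics and
sensible inductive bias, not performance on real tissue.

## Preprocessing

Highly variable genes are ranked by the Seurat v3 variance-stabilizing
criterion: a local regression of log10 variance on log10 mean across
genes (lowess, span 0.3), counts standardized by the trend-predicted
standard deviation and clipped at √n, genes ranked by the variance of the
clipped values, ties keeping input order. The top 3000 (or all, if fewer)
genes are kept identically and in identical order for both the count
target and the encoder input. The encoder input is library-size
normalized to the median library, log1p-transformed and per-gene
standardized with values clipped at ±10; the clip bounds outlier leverage
and is configurable. Spots with zero total counts are rejected with their
identifiers listed rather than silently dropped, keeping the
coordinate/matrix alignment explicit. No mitochondrial or spike-in
filtering is applied.

## Numerical choices and problem sizes

* Probabilities inside logarithms floored at 1e-12; row-normalization
  guard ε = 1e-12; parameter clamps as above with zero outside gradient.
* Cosine ties and K-means restarts resolved deterministically (lower
  index / seeded restarts).
* The test and acceptance workloads run the benchmark at 1000 spots ×
  200 genes, 100 training epochs (early stopping typically halts around
  epoch 70) for recovery and 60 epochs for the five-arm ablation
  comparison, five seeds each — sizes chosen so the full suite completes
  comfortably on a single CPU while leaving the recovery-vs-baseline gap
  measurable.

## Known limitations

* The feature graph is built once from the preprocessed expression and
  frozen; it is not rebuilt as embeddings improve.
* Hard-negative mining is O(n²) per epoch; fine at tissue-section scale,
  a cost at atlas scale.
* Whether the fused embedding's final linear layer carries a bias or
  activation, and whether imputation should return μ or (1−π)μ, are
  genuinely open conventions; the defaults (bias-free linear, μ) are
  flagged and configurable.
* Determinism is guaranteed on CPU for a fixed machine and seed, not
  across BLAS builds.
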