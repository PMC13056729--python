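# spatialdg

Spatial domain identification for spatially resolved transcriptomics by
dual-graph contrastive representation learning.

Array-based spatial transcriptomics (10x Visium, Stereo-seq, Slide-seqV2)
yields a UMI count vector and a 2-D position for every capture spot.
`spatialdg` recovers **spatial domains** — contiguous tissue regions with a
shared expression program, such as cortical layers or tumor compartments —
without supervision. It is aimed at computational biologists analyzing
tissue sections who want spatially coherent clusters, denoised expression,
and embeddings usable for downstream trajectory or visualization tools.

## Model

Two binary graphs are built over the n spots: a **spatial graph** A_s
(Euclidean distance ≤ r; r = 550 covers a Visium spot's six hexagonal
neighbors) and a **feature graph** A_f (union-symmetrized k = 15 nearest
neighbors under cosine similarity of expression). Three two-layer GCN
branches (d′ → 128 → 64) encode the preprocessed expression X: one per
graph plus a co-convolution branch whose shared weights propagate over
both graphs, H_c = (H_sc + H_fc)/2, with a consistency penalty
‖R_sc R_scᵀ − R_fc R_fcᵀ‖²_F on the row-normalized co-embeddings. A
per-spot attention softmax across the three views fuses them into H.

Training jointly minimizes

    L_total = α·L_ZINB + β·L_con + γ·L_reg + δ·L_DGI
    (α = 10.0, β = 0.1, γ = 0.1, δ = 0.15)

where L_ZINB is the zero-inflated negative binomial negative
log-likelihood of the raw counts under decoded per-spot-per-gene
(π, μ, θ); L_reg attracts spatial neighbors and repels sampled
non-neighbors; and L_DGI is a Deep-Graph-Infomax objective in which a
bilinear discriminator with a spatial-degree bias tells true
(spot, global-summary) pairs from **hard negatives** — each spot's most
cosine-similar non-neighbor, re-mined every epoch. Domains are called by
K-means (k-means++, 10 restarts) on H; agreement with ground truth is
scored by the adjusted Rand index (ARI). Full model details, defaults and
design choices are in [docs/methods.md](docs/methods.md).

The neural components run on a small reverse-mode autodiff engine over
NumPy (`spatialdg.autodiff`), gradient-checked against finite differences
in the test suite; no GPU or deep-learning framework is required.

## Worked example

Simulate a ground-truthed section (1000 hex spots, 5 stripe domains, 200
genes, 30% dropout) and run the full workflow:

```bash
$ spatialdg simulate --preset easy --seed 0 --out demo.h5ad
wrote 1000 spots x 200 genes to demo.h5ad (suggested spatial radius: 120)

$ spatialdg run --input demo.h5ad --out demo_out --clusters 5 \
      --radius 120 --knn 15 --seed 0
ARI vs ground truth: 1.0000
done: 5 domains over 1000 spots -> demo_out
```

The ARI of 1.0 means the five recovered domains match the generative
stripe labels exactly (expression-only PCA + K-means reaches ≈ 0.95 on
the same section — the spatial graphs close the remaining gap).
`demo_out/` contains `result.h5ad` (embeddings in `obsm["X_spatialdg"]`,
domains in `obs["spatialdg_domain"]`, denoised expression in
`layers["spatialdg_imputed"]`), a flat `domains.csv`
(spot_id, x, y, domain), the per-epoch loss `history.csv`, a weight
checkpoint, and the resolved `config.yaml`.

The same workflow is available as a library:

```python
import spatialdg as sdg

ds = sdg.easy_benchmark(seed=0)
res = sdg.run_pipeline(ds, n_domains=5,
                       graph_cfg=sdg.GraphConfig(radius=120, knn=15),
                       train_cfg=sdg.TrainConfig(max_epochs=100, seed=0))
print(res.ari)          # 1.0
res.domains.labels      # per-spot domain calls
```

For real data, `sdg.load_dataset("section.h5ad")` reads AnnData with
coordinates in `obsm["spatial"]` (MatrixMarket directories and CSV pairs
are also supported), and `--radius 550 --knn 15` are the Visium-scale
defaults.

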