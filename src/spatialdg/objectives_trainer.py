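"""Loss assembly and the full-batch training loop.

The total objective is the weighted sum

    L_total = alpha * L_ZINB + beta * L_con + gamma * L_reg + delta * L_DGI

with alpha=10.0, beta=0.1, gamma=0.1, delta=0.15 by default. The logged
components are size-normalized so the weights express a meaningful
balance: the ZINB likelihood per matrix entry, the consistency penalty per
Gram-matrix entry, the spatial regularizer per positive edge, and the DGI
loss (already a per-spot mean). Training is full batch with Adam
(lr 1e-3, weight decay 1e-5), at most 200 epochs, early stopping on the
reconstruction loss, and gradient clipping at global norm 5.0. Hard
negatives and the repulsion pairs of the spatial regularizer are resampled
every epoch. All randomness derives from one seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .autodiff import Adam, Tensor, clip_grad_norm
from .contrastive import (ContrastState, contrast_projection, dgi_loss,
                          select_hard_negatives, spatial_bias,
                          spatial_readout)
from .encoder import EncoderState, consistency_loss, encode
from .graphs import DualGraph
from .io_preprocess import SpotDataset
from .zinb_decoder import ZINBHeads, zinb_heads, zinb_nll


@dataclass
class LossWeights:
    alpha: float = 10.0          # ZINB reconstruction
    beta: float = 0.1            # cross-view consistency
    gamma: float = 0.1           # spatial regularization
    delta: float = 0.15          # DGI contrastive term
    lambda_reg: float = 0.1      # repulsion balance inside L_reg
    lambda_spatial: float = 0.0  # smoothness inside L_DGI (off: already in L_reg)

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"loss weight {name} must be >= 0")


@dataclass
class LossReport:
    epoch: int
    l_zinb: float
    l_con: float
    l_reg: float
    l_dgi: float
    l_total: float
    l_mse: float = 0.0           # only under the ZINB ablation


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-5
    max_epochs: int = 200
    patience: int = 20
    min_delta: float = 1e-4      # relative improvement threshold
    seed: int = 0
    hidden_dims: tuple = (128, 64)
    dropout: float = 0.1
    clip_norm: Optional[float] = 5.0
    restore_best: bool = True

    def __post_init__(self):
        self.hidden_dims = tuple(self.hidden_dims)
        if len(self.hidden_dims) != 2:
            raise ValueError("hidden_dims must be a pair")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        # keep the invariant patience < max_epochs even for short runs
        self.patience = max(1, min(self.patience, self.max_epochs - 1))


@dataclass
class AblationFlags:
    """Component switches mirroring the published ablations."""

    dual_graph: bool = True
    dgi: bool = True
    consistency: bool = True
    zinb: bool = True

    def apply(self, weights: LossWeights) -> LossWeights:
        w = copy.copy(weights)
        if not self.dgi:
            w.delta = 0.0
        if not self.consistency:
            w.beta = 0.0
        if not self.zinb:
            w.alpha = 0.0
        if w.alpha == 0 and w.beta == 0 and w.gamma == 0 and w.delta == 0 \
                and self.zinb:
            raise ValueError("all loss terms disabled")
        return w


def ablate(flags: AblationFlags,
           weights: Optional[LossWeights] = None) -> LossWeights:
    """Return the loss weights configured for an ablated trainer."""
    return flags.apply(weights or LossWeights())


def spatial_reg_loss(H: Tensor, E_spatial: np.ndarray, E_neg: np.ndarray,
                     lambda_reg: float) -> Tensor:
    """Neighbor attraction minus sampled non-neighbor repulsion.

    sum over positive edges of ||h_i - h_j||^2 / 2 minus lambda_reg times
    the same half-sum over the sampled negative pairs.
    """
    E_spatial = np.asarray(E_spatial).reshape(-1, 2)
    E_neg = np.asarray(E_neg).reshape(-1, 2)
    for name, E in (("E_spatial", E_spatial), ("E_neg", E_neg)):
        if E.size and np.any(E[:, 0] == E[:, 1]):
            raise ValueError(f"{name} contains self-pairs")
    if E_spatial.size and E_neg.size:
        pos = {(min(i, j), max(i, j)) for i, j in E_spatial}
        neg = {(min(i, j), max(i, j)) for i, j in E_neg}
        if pos & neg:
            raise ValueError("E_spatial and E_neg overlap")
    loss = Tensor(0.0)
    if E_spatial.size:
        d = H[E_spatial[:, 0]] - H[E_spatial[:, 1]]
        loss = loss + (d * d).sum() / 2.0
    if lambda_reg and E_neg.size:
        d = H[E_neg[:, 0]] - H[E_neg[:, 1]]
        loss = loss - lambda_reg * (d * d).sum() / 2.0
    return loss


def sample_negative_pairs(A_s: sp.spmatrix, m: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform (i, k) pairs with i != k and no spatial edge between them."""
    n = A_s.shape[0]
    A = sp.csr_matrix(A_s)
    out = np.empty((m, 2), dtype=np.int64)
    got = 0
    while got < m:
        cand = rng.integers(n, size=(2 * (m - got) + 8, 2))
        cand = cand[cand[:, 0] != cand[:, 1]]
        if cand.size:
            adj = np.asarray(A[cand[:, 0], cand[:, 1]]).ravel()
            cand = cand[adj == 0]
        take = min(len(cand), m - got)
        out[got:got + take] = cand[:take]
        got += take
    return out


def total_loss(l_zinb: float, l_con: float, l_reg: float, l_dgi: float,
               weights: LossWeights) -> float:
    """Weighted sum of the four components; aborts on a NaN term."""
    comps = {"l_zinb": l_zinb, "l_con": l_con, "l_reg": l_reg,
             "l_dgi": l_dgi}
    for name, v in comps.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component {name}={v}")
    return (weights.alpha * l_zinb + weights.beta * l_con
            + weights.gamma * l_reg + weights.delta * l_dgi)


@dataclass
class TrainResult:
    encoder: EncoderState
    contrast: ContrastState
    heads: ZINBHeads
    history: list
    embeddings: np.ndarray       # fused H from a final eval-mode pass
    graph: DualGraph = field(repr=False, default=None)


def _single_view(G: DualGraph) -> DualGraph:
    """Replace the feature graph by the spatial graph (dual-graph ablation)."""
    return DualGraph(A_s=G.A_s, A_f=G.A_s,
                     A_s_norm=G.A_s_norm, A_f_norm=G.A_s_norm)


def train(ds: SpotDataset, G: DualGraph, cfg: Optional[TrainConfig] = None,
          weights: Optional[LossWeights] = None,
          flags: Optional[AblationFlags] = None) -> TrainResult:
    """End-to-end full-batch training of encoder, contrast module and decoder.

    Early stopping monitors the reconstruction loss: training stops after
    ``patience`` consecutive epochs without a relative improvement of at
    least ``min_delta``, restoring the best-loss weights when configured.
    """
    cfg = cfg or TrainConfig()
    flags = flags or AblationFlags()
    weights = (weights or LossWeights())
    weights = flags.apply(weights)
    if ds.expr is None:
        raise ValueError("dataset must be preprocessed first")
    if not flags.dual_graph:
        G = _single_view(G)

    n, d = ds.counts.shape
    X = Tensor(ds.expr)
    counts = np.asarray(ds.counts)
    expr_target = Tensor(ds.expr)  # Gaussian target under the ZINB ablation
    rng = np.random.default_rng(cfg.seed)
    enc = EncoderState.init(ds.expr.shape[1], cfg.hidden_dims,
                            cfg.dropout, rng)
    con = ContrastState.init(cfg.hidden_dims[-1], rng)
    heads = ZINBHeads.init(cfg.hidden_dims[-1], d, rng)
    mse_head = None
    if not flags.zinb:
        from .autodiff import glorot, zeros
        mse_head = [glorot(rng, cfg.hidden_dims[-1], ds.expr.shape[1]),
                    zeros(ds.expr.shape[1])]
    params = enc.parameters() + con.parameters() + heads.parameters() \
        + (mse_head or [])
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    E_pos = G.spatial_edges
    n_edges = max(len(E_pos), 1)
    pos_set = None  # lazily built for overlap-free negative resampling
    history: list = []
    best = (np.inf, None, -1)  # (monitored loss, snapshot, epoch)
    stale = 0

    for epoch in range(cfg.max_epochs):
        emb = encode(X, G, enc, mode="train", rng=rng)
        h_contrast = contrast_projection(emb.weighted, con)

        # --- reconstruction -------------------------------------------------
        l_mse_t = None
        if flags.zinb:
            zp = zinb_heads(emb.H, heads)
            l_zinb_t = zinb_nll(counts, zp) / (n * d)
        else:
            l_zinb_t = Tensor(0.0)
            recon = emb.H @ mse_head[0] + mse_head[1]
            diff = recon - expr_target
            l_mse_t = (diff * diff).mean()

        # --- consistency ----------------------------------------------------
        if weights.beta:
            l_con_t = consistency_loss(emb.H_sc, emb.H_fc) / (n * n)
        else:
            l_con_t = Tensor(0.0)

        # --- spatial regularization -----------------------------------------
        if weights.gamma and len(E_pos):
            if pos_set is None:
                pos_set = {(i, j) for i, j in E_pos}
            E_neg = sample_negative_pairs(G.A_s, len(E_pos), rng)
            l_reg_t = spatial_reg_loss(emb.H, E_pos, E_neg,
                                       weights.lambda_reg) / n_edges
        else:
            l_reg_t = Tensor(0.0)

        # --- DGI -------------------------------------------------------------
        if weights.delta:
            neg_index = select_hard_negatives(
                h_contrast.data, G.A_s, G.A_f,
                rng_seed=int(rng.integers(2**31)))
            s, _ = spatial_readout(h_contrast, G.A_s)
            bias = spatial_bias(G.A_s, con.b0)
            l_dgi_t = dgi_loss(h_contrast, neg_index, s, bias,
                               con.W_spatial, G.A_s, weights.lambda_spatial)
        else:
            l_dgi_t = Tensor(0.0)

        total_t = (weights.alpha * l_zinb_t + weights.beta * l_con_t
                   + weights.gamma * l_reg_t + weights.delta * l_dgi_t)
        if l_mse_t is not None:
            total_t = total_t + l_mse_t

        report = LossReport(
            epoch=epoch,
            l_zinb=l_zinb_t.item(), l_con=l_con_t.item(),
            l_reg=l_reg_t.item(), l_dgi=l_dgi_t.item(),
            l_total=total_t.item(),
            l_mse=0.0 if l_mse_t is None else l_mse_t.item(),
        )
        if not np.isfinite(report.l_total):
            bad = [k for k in ("l_zinb", "l_con", "l_reg", "l_dgi", "l_mse")
                   if not np.isfinite(getattr(report, k))]
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {', '.join(bad)}")
        history.append(report)

        opt.zero_grad()
        total_t.backward()
        if cfg.clip_norm:
            clip_grad_norm(params, cfg.clip_norm)
        opt.step()

        # --- early stopping on the reconstruction loss ----------------------
        monitored = report.l_zinb if flags.zinb else report.l_mse
        ref = abs(best[0]) if np.isfinite(best[0]) else 1.0
        if monitored < best[0] - cfg.min_delta * max(ref, 1e-12):
            best = (monitored, [p.data.copy() for p in params], epoch)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    if cfg.restore_best and best[1] is not None:
        for p, data in zip(params, best[1]):
            p.data = data

    emb = encode(X, G, enc, mode="eval")
    return TrainResult(encoder=enc, contrast=con, heads=heads,
                       history=history, embeddings=emb.H.data.copy(),
                       graph=G)


def history_to_csv(history: list, path: str) -> None:
    """Write the per-epoch loss history as CSV."""
    import pandas as pd
    pd.DataFrame([asdict(r) for r in history]).to_csv(path, index=False)
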