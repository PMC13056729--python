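"""Multi-view graph-convolutional encoder with attention fusion.

Three two-layer GCN branches share the input X: a spatial branch over the
spatial graph, a feature branch over the expression-similarity graph, and a
co-convolution branch that propagates over both graphs with one shared
weight matrix, whose two outputs are averaged into the common embedding
H_c and tied together by a consistency penalty on their row-normalized
Gram matrices. A per-spot attention softmax across the three views yields
convex combination weights, and a final bias-free linear layer produces
the fused embedding H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from . import autodiff as _ad
from .autodiff import Tensor, dropout, glorot, spmm, zeros
from .graphs import DualGraph

HIDDEN_DIMS = (128, 64)
ATTENTION_DIM = 64
DROPOUT_RATE = 0.1


@dataclass
class EncoderState:
    """All learnable encoder weights plus the dropout rate."""

    W_s: list                 # per-layer spatial-branch weights
    W_f: list                 # per-layer feature-branch weights
    W_c: list                 # per-layer shared co-convolution weights
    att_W: Tensor             # attention transform (embed -> attention dim)
    att_b: Tensor             # attention bias
    W_co: Tensor              # shared attention vector (attention dim -> 1)
    F_weights: Tensor         # final bias-free fusion layer (embed -> embed)
    dropout_rate: float = DROPOUT_RATE

    def parameters(self) -> list:
        return [*self.W_s, *self.W_f, *self.W_c,
                self.att_W, self.att_b, self.W_co, self.F_weights]

    @classmethod
    def init(cls, input_dim: int, hidden_dims=HIDDEN_DIMS,
             dropout_rate: float = DROPOUT_RATE,
             rng: Optional[np.random.Generator] = None) -> "EncoderState":
        rng = rng or np.random.default_rng()
        dims = (input_dim, *hidden_dims)
        layers = list(zip(dims[:-1], dims[1:]))
        emb = hidden_dims[-1]
        return cls(
            W_s=[glorot(rng, p, q) for p, q in layers],
            W_f=[glorot(rng, p, q) for p, q in layers],
            W_c=[glorot(rng, p, q) for p, q in layers],
            att_W=glorot(rng, emb, ATTENTION_DIM),
            att_b=zeros(ATTENTION_DIM),
            W_co=glorot(rng, ATTENTION_DIM, 1),
            F_weights=glorot(rng, emb, emb),
            dropout_rate=dropout_rate,
        )


@dataclass
class EmbeddingSet:
    """Per-forward embeddings of one encoder pass (autodiff tensors)."""

    H_s: Tensor
    H_f: Tensor
    H_sc: Tensor
    H_fc: Tensor
    H_c: Tensor
    a_s: Tensor               # (n, 1) attention coefficients
    a_f: Tensor
    a_c: Tensor
    H: Tensor                 # fused embedding
    weighted: Tensor = field(repr=False, default=None)  # pre-fusion sum


def gcn_layer(H_in: Tensor, A_norm: sp.spmatrix, W_layer: Tensor,
              activate: bool = True) -> Tensor:
    """One propagation step ReLU(A_norm @ H_in @ W_layer)."""
    if H_in.shape[1] != W_layer.shape[0]:
        raise ValueError(
            f"dimension mismatch: H_in has {H_in.shape[1]} columns, "
            f"W_layer expects {W_layer.shape[0]}"
        )
    out = spmm(A_norm, H_in) @ W_layer
    return out.relu() if activate else out


def _branch(X: Tensor, A_norm, weights, rate, rng, train) -> Tensor:
    H = gcn_layer(X, A_norm, weights[0], activate=True)
    H = dropout(H, rate, rng, train)  # after the first layer only
    return gcn_layer(H, A_norm, weights[1], activate=True)


def attention_fuse(H_s: Tensor, H_f: Tensor, H_c: Tensor,
                   state: EncoderState):
    """Per-spot softmax attention across the three views, then fusion.

    Each view's score is the shared attention vector applied to a tanh
    transform of its embedding; the softmax over the three scores gives
    convex weights, and the weighted sum passes through the final linear
    layer F.
    """
    scores = [(H_v @ state.att_W + state.att_b).tanh() @ state.W_co
              for H_v in (H_s, H_f, H_c)]           # each (n, 1)
    m = np.max([s.data for s in scores], axis=0)    # constant shift
    exps = [(s - Tensor(m)).exp() for s in scores]
    denom = exps[0] + exps[1] + exps[2]
    a_s, a_f, a_c = (e / denom for e in exps)
    weighted = a_s * H_s + a_f * H_f + a_c * H_c
    H = weighted @ state.F_weights
    return a_s, a_f, a_c, H, weighted


def encode(X, G: DualGraph, state: EncoderState, mode: str = "eval",
           rng: Optional[np.random.Generator] = None) -> EmbeddingSet:
    """Full encoder forward pass over both graphs.

    ``mode="train"`` enables dropout (requires ``rng``); ``"eval"`` is
    deterministic. The co-convolution branch applies the same shared
    weights on both graphs, so gradients accumulate from both paths.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    train = mode == "train"
    if train and rng is None:
        raise ValueError("training mode requires an rng for dropout")
    X = X if isinstance(X, Tensor) else Tensor(X)
    rate = state.dropout_rate
    H_s = _branch(X, G.A_s_norm, state.W_s, rate, rng, train)
    H_f = _branch(X, G.A_f_norm, state.W_f, rate, rng, train)
    H_sc = _branch(X, G.A_s_norm, state.W_c, rate, rng, train)
    H_fc = _branch(X, G.A_f_norm, state.W_c, rate, rng, train)
    H_c = (H_sc + H_fc) / 2.0
    a_s, a_f, a_c, H, weighted = attention_fuse(H_s, H_f, H_c, state)
    return EmbeddingSet(H_s=H_s, H_f=H_f, H_sc=H_sc, H_fc=H_fc, H_c=H_c,
                        a_s=a_s, a_f=a_f, a_c=a_c, H=H, weighted=weighted)


def _row_normalize(H: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((H * H).sum(axis=1, keepdims=True) + eps).sqrt()
    return H / norm


def consistency_loss(H_sc: Tensor, H_fc: Tensor) -> Tensor:
    """Squared Frobenius distance between row-normalized Gram matrices.

    Invariant to positive per-row rescaling of either argument; zero iff
    the two views induce identical spot-spot cosine-similarity structure.
    """
    if H_sc.shape != H_fc.shape:
        raise ValueError("consistency_loss requires equal shapes")
    R1 = _row_normalize(H_sc)
    R2 = _row_normalize(H_fc)
    # fused ||R1 R1^T - R2 R2^T||_F^2 with the analytic gradient
    # (4 D R1, -4 D R2), exploiting symmetry of D to halve the work
    D = R1.data @ R1.data.T - R2.data @ R2.data.T

    def bw(g, out):
        return (g * 4.0 * (D @ R1.data), g * (-4.0) * (D @ R2.data))

    return _ad._op((R1, R2), (D * D).sum(), bw)
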