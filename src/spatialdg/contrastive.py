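"""Spatial-aware Deep Graph Infomax with adaptive hard-negative mining.

A degree-weighted readout pools node embeddings into a global summary s;
a bilinear discriminator with a spatial-degree bias scores (node, summary)
pairs; negatives are, for each spot, the most cosine-similar spot that is
neither itself nor a spatial or feature neighbor (falling back to a seeded
random draw when no candidate exists). The DGI objective is the standard
binary cross-entropy over positive and negative pairs plus an optional
neighbor-smoothness penalty. The contrastive loss operates on a projected
version of the attention-weighted embedding (one-hidden-layer MLP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, glorot, zeros

LOG_FLOOR = 1e-12
NEG_CHUNK = 512


@dataclass
class ContrastState:
    """Learnable weights of the contrastive module."""

    W_spatial: Tensor          # bilinear discriminator (embed x embed)
    b0: Tensor                 # scalar scale of the spatial degree bias
    mlp_W1: Tensor             # projection MLP, hidden layer
    mlp_b1: Tensor
    mlp_W2: Tensor
    mlp_b2: Tensor

    def parameters(self) -> list:
        return [self.W_spatial, self.b0, self.mlp_W1, self.mlp_b1,
                self.mlp_W2, self.mlp_b2]

    @classmethod
    def init(cls, embed_dim: int = 64,
             rng: Optional[np.random.Generator] = None) -> "ContrastState":
        rng = rng or np.random.default_rng()
        return cls(
            W_spatial=glorot(rng, embed_dim, embed_dim),
            b0=zeros(1),
            mlp_W1=glorot(rng, embed_dim, embed_dim),
            mlp_b1=zeros(embed_dim),
            mlp_W2=glorot(rng, embed_dim, embed_dim),
            mlp_b2=zeros(embed_dim),
        )


def contrast_projection(weighted: Tensor, state: ContrastState) -> Tensor:
    """One-hidden-layer MLP on the attention-weighted embedding sum."""
    hidden = (weighted @ state.mlp_W1 + state.mlp_b1).relu()
    return hidden @ state.mlp_W2 + state.mlp_b2


def spatial_readout(H: Tensor, A_s: sp.spmatrix):
    """Degree-weighted global summary.

    Spot weights are 1 + spatial degree (so isolated spots still
    contribute); the weighted mean is sigmoid-squashed to keep the summary
    bounded for the bilinear discriminator. Returns (s, w) with s a
    (d, 1) tensor and w the plain weight vector.
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    w = 1.0 + np.asarray(A_s.sum(axis=1)).ravel()
    wt = Tensor(w[:, None])
    s = ((wt * H).sum(axis=0, keepdims=True) / w.sum()).T.sigmoid()
    return s, w


def spatial_bias(A_s: sp.spmatrix, b0: Tensor) -> Tensor:
    """Per-spot discriminator bias: b0 * degree / max degree."""
    deg = np.asarray(A_s.sum(axis=1)).ravel()
    mx = deg.max()
    scaled = deg / mx if mx > 0 else np.zeros_like(deg)
    return b0 * Tensor(scaled[:, None])


def discriminate(h_i, s, bias_i, W_spatial) -> Tensor:
    """sigmoid(h_i^T W_spatial s + bias_i) for a single spot."""
    h_i = h_i if isinstance(h_i, Tensor) else Tensor(np.asarray(h_i))
    s = s if isinstance(s, Tensor) else Tensor(np.asarray(s))
    logits = (h_i.reshape(1, -1) @ W_spatial @ s.reshape(-1, 1)).reshape(1)
    return (logits + bias_i).sigmoid()


def _discriminate_all(H: Tensor, s: Tensor, bias: Tensor,
                      W_spatial: Tensor) -> Tensor:
    """Vectorized discriminator over all spots; returns (n, 1) scores."""
    return (H @ W_spatial @ s + bias).sigmoid()


def select_hard_negatives(H: np.ndarray, A_s: sp.spmatrix, A_f: sp.spmatrix,
                          rng_seed: int) -> np.ndarray:
    """For each spot, the most cosine-similar non-neighbor.

    The exclusion set of spot i is itself plus its spatial and feature
    neighbors; among the remaining candidates the one with the highest
    cosine similarity wins (ties to the lower index). Spots with no
    candidates draw a uniform random j != i from a seeded generator.
    Computed in row blocks; results are identical to the full-matrix scan.
    """
    H = np.asarray(H, dtype=np.float64)
    n = H.shape[0]
    if n < 2:
        raise ValueError("need at least two spots to mine negatives")
    rng = np.random.default_rng(rng_seed)
    norms = np.linalg.norm(H, axis=1)
    norms[norms == 0] = 1.0
    Hn = H / norms[:, None]
    excl = ((A_s + A_f) != 0).tolil().rows  # neighbor lists per row
    neg = np.empty(n, dtype=np.int64)
    fallback = []
    for start in range(0, n, NEG_CHUNK):
        stop = min(start + NEG_CHUNK, n)
        S = Hn[start:stop] @ Hn.T
        for i in range(start, stop):
            row = S[i - start]
            row[i] = -np.inf
            row[excl[i]] = -np.inf
            j = int(np.argmax(row))
            if np.isinf(row[j]):
                fallback.append(i)
                neg[i] = -1
            else:
                neg[i] = j
    for i in fallback:  # empty candidate set: seeded random j != i
        j = int(rng.integers(n - 1))
        neg[i] = j if j < i else j + 1
    return neg


def dgi_loss(H: Tensor, neg_index: np.ndarray, s: Tensor, bias: Tensor,
             W_spatial: Tensor, A_s: sp.spmatrix,
             lambda_spatial: float = 0.0) -> Tensor:
    """Contrastive DGI objective with an optional spatial smoothness term.

    -(1/n) sum_i [log D(h_i, s) + log(1 - D(h_neg_i, s))], log arguments
    floored at 1e-12, plus lambda_spatial * sum over undirected spatial
    edges of the squared embedding distance.
    """
    n = H.shape[0]
    pos = _discriminate_all(H, s, bias, W_spatial)
    neg = _discriminate_all(H[neg_index], s, bias, W_spatial)
    loss = -(pos.clamp(lo=LOG_FLOOR).log()
             + (1.0 - neg).clamp(lo=LOG_FLOOR).log()).sum() / n
    if lambda_spatial:
        coo = sp.triu(A_s, k=1).tocoo()
        if coo.nnz:
            diff = H[coo.row] - H[coo.col]
            loss = loss + lambda_spatial * (diff * diff).sum()
    return loss
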