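"""Spatial domain calling on learned embeddings and agreement scoring.

Domains are called by K-means (k-means++ initialization, best of several
restarts by within-cluster sum of squares) on the fused embeddings; the
number of domains K is user input, typically from prior biological
knowledge. Agreement with ground truth is quantified by the adjusted Rand
index. An optional one-pass majority-vote smoothing over spatial
neighbors is provided but disabled by default so the headline behavior is
the raw K-means partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score


@dataclass
class DomainAssignment:
    labels: np.ndarray        # (n,) integers in [0, K)
    K: int
    centroids: np.ndarray     # (K, embed_dim)
    inertia: float = np.nan   # within-cluster sum of squares


def cluster_domains(H: np.ndarray, K: int, seed: int = 0,
                    restarts: int = 10) -> DomainAssignment:
    """K-means domain calling, best of ``restarts`` seeded runs by WCSS."""
    H = np.asarray(H, dtype=np.float64)
    n = H.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of spots n={n}")
    if K < 1 or restarts < 1:
        raise ValueError("K and restarts must be positive")
    km = KMeans(n_clusters=K, init="k-means++", n_init=restarts,
                random_state=seed).fit(H)
    return DomainAssignment(labels=km.labels_.astype(np.int64), K=K,
                            centroids=km.cluster_centers_,
                            inertia=float(km.inertia_))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (chance-corrected)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("labelings must be non-empty and of equal length")
    return float(adjusted_rand_score(a, b))


def refine_spatial(labels, A_s: sp.spmatrix, enabled: bool = False) -> np.ndarray:
    """One-pass strict-majority smoothing over spatial neighborhoods.

    A spot adopts the most frequent label among its spatial neighbors only
    when that label disagrees with its own and covers more than half of
    the neighborhood; ties never relabel. Disabled by default.
    """
    labels = np.asarray(labels).copy()
    if not enabled:
        return labels
    A = sp.csr_matrix(A_s)
    out = labels.copy()
    for i in range(len(labels)):
        nbrs = A.indices[A.indptr[i]:A.indptr[i + 1]]
        if nbrs.size == 0:
            continue
        vals, counts = np.unique(labels[nbrs], return_counts=True)
        top = counts.max()
        if top * 2 > nbrs.size and (counts == top).sum() == 1:
            winner = vals[np.argmax(counts)]
            if winner != labels[i]:
                out[i] = winner
    return out
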