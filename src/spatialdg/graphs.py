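"""Construction of the spatial and feature adjacency graphs.

The spatial graph connects spots whose Euclidean distance is at most a
radius r (inclusive); the feature graph links each spot to its k most
cosine-similar spots and is symmetrized by union. Both are binary with a
zero diagonal. ``normalize_adjacency`` produces the self-loop-augmented
symmetric normalization D̃^{-1/2} (A + I) D̃^{-1/2} used by every graph
convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics.pairwise import cosine_similarity
from sklearn.neighbors import radius_neighbors_graph

#: radius covering the central spot plus its six immediate hexagonal
#: neighbors on a standard Visium section; Slide-seqV2-scale coordinates
#: use RADIUS_SLIDESEQ instead.
RADIUS_VISIUM = 550.0
RADIUS_SLIDESEQ = 50.0
DEFAULT_KNN = 15


@dataclass
class GraphConfig:
    radius: float = RADIUS_VISIUM
    knn: int = DEFAULT_KNN

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.knn < 1:
            raise ValueError("knn must be >= 1")


@dataclass
class DualGraph:
    """Spatial and feature adjacency plus their normalized forms."""

    A_s: sp.csr_matrix
    A_f: sp.csr_matrix
    A_s_norm: sp.csr_matrix
    A_f_norm: sp.csr_matrix

    @property
    def n_spots(self) -> int:
        return self.A_s.shape[0]

    @property
    def spatial_degrees(self) -> np.ndarray:
        return np.asarray(self.A_s.sum(axis=1)).ravel()

    @property
    def spatial_edges(self) -> np.ndarray:
        """Undirected spatial edge list, each edge once, as an (m, 2) array."""
        coo = sp.triu(self.A_s, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])


def build_spatial_graph(coords: np.ndarray, r: float) -> sp.csr_matrix:
    """Binary adjacency: spots i != j with Euclidean distance <= r."""
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if r <= 0:
        raise ValueError("radius must be > 0")
    n = coords.shape[0]
    if n == 1:
        return sp.csr_matrix((1, 1))
    A = radius_neighbors_graph(coords, radius=r, mode="connectivity",
                               include_self=False)
    A = A.maximum(A.T)  # guard symmetry against floating-point asymmetries
    A.data[:] = 1.0
    return sp.csr_matrix(A)


def build_feature_graph(X: np.ndarray, k: int) -> sp.csr_matrix:
    """Union-symmetrized kNN graph under cosine similarity of expression.

    Each spot is linked to its k most similar other spots (ties broken by
    lower spot index); the directed graph is symmetrized by union, so every
    row keeps between k and 2k neighbors.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"all-zero expression rows (cosine undefined): "
                         f"spots {zero.tolist()}")
    S = cosine_similarity(X)
    np.fill_diagonal(S, -np.inf)
    # stable sort on -S: equal similarities resolve to the lower index
    nbrs = np.argsort(-S, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, nbrs.ravel())), shape=(n, n))
    A = A.maximum(A.T)
    A.data[:] = 1.0
    return A


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Self-loop-augmented symmetric normalization D̃^{-1/2} (A+I) D̃^{-1/2}."""
    A = sp.csr_matrix(A, dtype=np.float64)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A - A.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    At = A + sp.identity(A.shape[0], format="csr")
    deg = np.asarray(At.sum(axis=1)).ravel()
    dinv = sp.diags(1.0 / np.sqrt(deg))
    return sp.csr_matrix(dinv @ At @ dinv)


def build_dual_graph(coords: np.ndarray, X: np.ndarray,
                     cfg: GraphConfig) -> DualGraph:
    A_s = build_spatial_graph(coords, cfg.radius)
    A_f = build_feature_graph(X, cfg.knn)
    return DualGraph(A_s=A_s, A_f=A_f,
                     A_s_norm=normalize_adjacency(A_s),
                     A_f_norm=normalize_adjacency(A_f))


def export_edgelist(A: sp.spmatrix, path: str) -> None:
    """Write a graph as a TSV edge list (i, j, weight), each edge once."""
    coo = sp.triu(A, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{w:g}\n")
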