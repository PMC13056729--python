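"""Reading, writing, and preprocessing of spatial transcriptomics datasets.

A :class:`SpotDataset` bundles the raw UMI count matrix, the preprocessed
encoder input, the 2-D spot coordinates and optional ground-truth domain
labels for one tissue section. Inputs are read from h5ad (AnnData on disk,
coordinates in ``obsm["spatial"]``), from a MatrixMarket directory, or from
a pair of CSVs. Preprocessing selects highly variable genes by the Seurat
v3 variance-stabilizing ranking, library-size normalizes to the median
library, log-transforms, and scales each gene to zero mean / unit variance
(clipped at ±10), keeping the raw counts of the same genes as the
reconstruction target for the count model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

LABEL_KEY = "ground_truth"
DOMAIN_KEY = "spatialdg_domain"
EMBED_KEY = "X_spatialdg"
IMPUTED_LAYER = "spatialdg_imputed"


@dataclass
class SpotDataset:
    """One tissue section: counts, processed expression, coordinates, labels.

    ``expr`` is None until :func:`preprocess` has been applied; ``true_mean``
    holds the generative mean matrix for synthetic data only.
    """

    counts: np.ndarray                      # (n, d) non-negative integers
    coords: np.ndarray                      # (n, 2)
    gene_names: list = field(default_factory=list)
    spot_ids: list = field(default_factory=list)
    expr: Optional[np.ndarray] = None       # (n, d') preprocessed input
    labels: Optional[np.ndarray] = None     # (n,) integer domains
    true_mean: Optional[np.ndarray] = None  # (n, d) synthetic ground truth

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        n, d = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if not self.gene_names:
            self.gene_names = [f"gene_{j}" for j in range(d)]
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if len(self.gene_names) != d or len(self.spot_ids) != n:
            raise ValueError("gene_names/spot_ids lengths do not match matrix")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicated spot_ids")
        _validate_counts(self.counts, self.spot_ids, self.gene_names)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def _validate_counts(counts, spot_ids, gene_names):
    bad = np.argwhere((counts < 0) | (counts != np.floor(counts)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"counts must be non-negative integers; offending cell "
            f"(spot={spot_ids[i]}, gene={gene_names[j]}) = {counts[i, j]}"
        )


# --------------------------------------------------------------------- loading

def load_dataset(path: str, format: Optional[str] = None) -> SpotDataset:
    """Load a dataset from ``h5ad``, ``mtx_dir`` or ``csv_pair``.

    The format is inferred from the path when not given: a ``.h5ad`` file,
    a directory containing ``matrix.mtx``, or a counts CSV whose sibling
    ``<stem>.coords.csv`` holds spot coordinates.
    """
    if format is None:
        if str(path).endswith(".h5ad"):
            format = "h5ad"
        elif os.path.isdir(path):
            format = "mtx_dir"
        else:
            format = "csv_pair"
    if format == "h5ad":
        return _load_h5ad(path)
    if format == "mtx_dir":
        return _load_mtx_dir(path)
    if format == "csv_pair":
        return _load_csv_pair(path)
    raise ValueError(f"unknown format {format!r}")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def _load_h5ad(path: str) -> SpotDataset:
    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise ValueError("no spatial coordinates (obsm['spatial'] missing)")
    counts = _dense(adata.layers["counts"]) if "counts" in adata.layers \
        else _dense(adata.X)
    labels = None
    if LABEL_KEY in adata.obs:
        labels = pd.Categorical(adata.obs[LABEL_KEY]).codes.astype(int)
    true_mean = _dense(adata.layers["true_mean"]) if "true_mean" in adata.layers \
        else None
    return SpotDataset(
        counts=np.rint(counts).astype(np.int64)
        if np.allclose(counts, np.rint(counts)) else counts,
        coords=np.asarray(adata.obsm["spatial"], dtype=float),
        gene_names=list(adata.var_names),
        spot_ids=list(adata.obs_names),
        labels=labels,
        true_mean=true_mean,
    )


def _load_mtx_dir(path: str) -> SpotDataset:
    mat = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t",
                        header=None)[0].tolist()
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t",
                           header=None)[0].tolist()
    coords_df = pd.read_csv(os.path.join(path, "coordinates.csv"))
    counts = _dense(mat)
    if counts.shape == (len(genes), len(barcodes)):
        counts = counts.T  # genes x barcodes convention
    if counts.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {counts.shape} inconsistent with "
            f"{len(barcodes)} barcodes x {len(genes)} genes"
        )
    coords_df = coords_df.set_index("spot_id").loc[barcodes]
    return SpotDataset(
        counts=counts.astype(np.int64),
        coords=coords_df[["x", "y"]].to_numpy(dtype=float),
        gene_names=genes,
        spot_ids=barcodes,
    )


def _load_csv_pair(path: str) -> SpotDataset:
    counts_df = pd.read_csv(path, index_col=0)
    stem = str(path)[: -len(".csv")] if str(path).endswith(".csv") else str(path)
    coords_df = pd.read_csv(stem + ".coords.csv").set_index("spot_id")
    coords_df = coords_df.loc[counts_df.index]
    return SpotDataset(
        counts=counts_df.to_numpy(dtype=np.int64),
        coords=coords_df[["x", "y"]].to_numpy(dtype=float),
        gene_names=list(counts_df.columns),
        spot_ids=list(counts_df.index),
    )


def to_anndata(ds: SpotDataset) -> ad.AnnData:
    adata = ad.AnnData(
        X=sp.csr_matrix(ds.counts.astype(np.float64)),
        obs=pd.DataFrame(index=ds.spot_ids),
        var=pd.DataFrame(index=ds.gene_names),
    )
    adata.obsm["spatial"] = ds.coords.copy()
    if ds.labels is not None:
        adata.obs[LABEL_KEY] = np.asarray(ds.labels)
    if ds.true_mean is not None:
        adata.layers["true_mean"] = ds.true_mean.copy()
    return adata


def save_dataset(ds: SpotDataset, path: str, embeddings=None, domains=None,
                 imputed=None) -> None:
    """Write a dataset (plus optional results) back to h5ad."""
    adata = to_anndata(ds)
    if embeddings is not None:
        adata.obsm[EMBED_KEY] = np.asarray(embeddings)
    if domains is not None:
        adata.obs[DOMAIN_KEY] = pd.Categorical(np.asarray(domains))
    if imputed is not None:
        adata.layers[IMPUTED_LAYER] = np.asarray(imputed)
    adata.write_h5ad(path)


# --------------------------------------------------------------- preprocessing

def seurat_v3_hvg_rank(counts: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Rank genes by the Seurat v3 variance-stabilizing criterion.

    Fits a local regression of log10(variance) on log10(mean) across genes,
    standardizes counts by the trend-predicted standard deviation with
    values clipped at sqrt(n), and ranks genes by the variance of the
    clipped standardized counts (descending; ties keep input gene order).
    Returns the gene indices in rank order.
    """
    X = np.asarray(counts, dtype=np.float64)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
    est_var = np.zeros_like(var)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 3:
        fit = lowess(np.log10(var[ok]), np.log10(mean[ok]), frac=span,
                     return_sorted=False)
        est_var[ok] = 10.0 ** fit
    else:
        est_var[ok] = var[ok]
    sd = np.sqrt(est_var)
    score = np.zeros(X.shape[1])
    clip_val = np.sqrt(n)
    which = np.flatnonzero(sd > 0)
    if which.size:
        Z = (X[:, which] - mean[which]) / sd[which]
        np.clip(Z, -clip_val, clip_val, out=Z)
        score[which] = (Z**2).sum(axis=0) / max(n - 1, 1)
    return np.argsort(-score, kind="stable")


def preprocess(ds: SpotDataset, n_hvg: int = 3000, clip: float = 10.0,
               span: float = 0.3) -> SpotDataset:
    """Select HVGs and build the normalized encoder input.

    Returns a new dataset with ``counts`` restricted to the selected genes
    (raw, the reconstruction target) and ``expr`` the library-size
    normalized (median target), log1p-transformed, per-gene standardized
    expression clipped at ±``clip``.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    lib = np.asarray(ds.counts, dtype=float).sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        ids = [ds.spot_ids[i] for i in zero]
        raise ValueError(f"spots with zero total count: {ids}; filter them first")
    keep = np.sort(seurat_v3_hvg_rank(ds.counts, span=span)[: min(n_hvg, ds.n_genes)])
    counts = np.asarray(ds.counts)[:, keep]

    adata = ad.AnnData(X=np.asarray(ds.counts, dtype=np.float64)[:, keep])
    sc.pp.normalize_total(adata, target_sum=None)  # median library size
    sc.pp.log1p(adata)
    sc.pp.scale(adata, max_value=clip)
    expr = np.ascontiguousarray(adata.X, dtype=np.float64)

    return SpotDataset(
        counts=counts,
        coords=ds.coords.copy(),
        gene_names=[ds.gene_names[j] for j in keep],
        spot_ids=list(ds.spot_ids),
        expr=expr,
        labels=None if ds.labels is None else np.asarray(ds.labels).copy(),
        true_mean=None if ds.true_mean is None else
        np.asarray(ds.true_mean)[:, keep],
    )
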