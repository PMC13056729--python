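"""End-to-end workflow: preprocess -> graphs -> train -> cluster -> impute."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clustering_eval import DomainAssignment, ari, cluster_domains
from .encoder import encode
from .graphs import GraphConfig, build_dual_graph
from .io_preprocess import SpotDataset, preprocess
from .objectives_trainer import (AblationFlags, LossWeights, TrainConfig,
                                 TrainResult, train)
from .zinb_decoder import impute_expression, zinb_heads

logger = logging.getLogger("spatialdg")


@dataclass
class PipelineResult:
    dataset: SpotDataset          # preprocessed
    train_result: TrainResult
    domains: DomainAssignment
    imputed: np.ndarray
    ari: Optional[float] = None   # vs ground truth when available
    embeddings: np.ndarray = field(default=None, repr=False)


def run_pipeline(ds: SpotDataset, n_domains: int,
                 graph_cfg: Optional[GraphConfig] = None,
                 train_cfg: Optional[TrainConfig] = None,
                 weights: Optional[LossWeights] = None,
                 flags: Optional[AblationFlags] = None,
                 n_hvg: int = 3000) -> PipelineResult:
    """Run the full workflow on a raw dataset and call spatial domains."""
    graph_cfg = graph_cfg or GraphConfig()
    train_cfg = train_cfg or TrainConfig()
    flags = flags or AblationFlags()

    if ds.expr is None:
        ds = preprocess(ds, n_hvg=n_hvg)
    G = build_dual_graph(ds.coords, ds.expr, graph_cfg)
    logger.info("graphs built: %d spatial edges, %d feature edges",
                G.A_s.nnz // 2, G.A_f.nnz // 2)

    result = train(ds, G, cfg=train_cfg, weights=weights, flags=flags)
    for rep in result.history:
        logger.info("epoch %d: zinb=%.5f con=%.5f reg=%.5f dgi=%.5f "
                    "total=%.5f", rep.epoch, rep.l_zinb, rep.l_con,
                    rep.l_reg, rep.l_dgi, rep.l_total)

    domains = cluster_domains(result.embeddings, n_domains,
                              seed=train_cfg.seed)
    emb = encode(ds.expr, result.graph, result.encoder, mode="eval")
    imputed = impute_expression(zinb_heads(emb.H, result.heads))

    score = None
    if ds.labels is not None:
        score = ari(ds.labels, domains.labels)
        logger.info("ARI vs ground truth: %.4f", score)
    return PipelineResult(dataset=ds, train_result=result, domains=domains,
                          imputed=imputed, ari=score,
                          embeddings=result.embeddings)


def pca_kmeans_baseline(ds: SpotDataset, n_domains: int, seed: int = 0,
                        n_components: int = 30) -> np.ndarray:
    """Expression-only baseline: K-means on a PCA of the processed input."""
    from sklearn.decomposition import PCA
    if ds.expr is None:
        ds = preprocess(ds)
    n_components = min(n_components, *ds.expr.shape)
    Z = PCA(n_components=n_components, random_state=seed).fit_transform(ds.expr)
    return cluster_domains(Z, n_domains, seed=seed).labels


def save_checkpoint(result: TrainResult, cfg: TrainConfig, path: str) -> None:
    """Persist all learned weights plus the training configuration as npz."""
    arrays = {}
    for group, obj in (("enc", result.encoder), ("con", result.contrast),
                       ("heads", result.heads)):
        for name, p in _named_params(obj):
            arrays[f"{group}.{name}"] = p.data
    np.savez(path, **arrays,
             _config=np.array([repr(cfg)], dtype=object))


def _named_params(obj):
    from .autodiff import Tensor
    for fname in obj.__dataclass_fields__:
        val = getattr(obj, fname)
        if isinstance(val, Tensor):
            yield fname, val
        elif isinstance(val, list) and val and isinstance(val[0], Tensor):
            for i, t in enumerate(val):
                yield f"{fname}.{i}", t
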