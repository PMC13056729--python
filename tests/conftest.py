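import numpy as np
import pytest

import spatialdg as sdg

# spatial-graph radius covering the first hexagonal neighbor shell of the
# synthetic layouts (spacing 100)
SYN_RADIUS = 120.0
BENCH_SEEDS = range(5)


@pytest.fixture(scope="session")
def small_raw():
    """150-spot, 3-domain synthetic section used by unit tests."""
    return sdg.generate(sdg.SimConfig(n_spots=150, K_true=3, n_genes=60,
                                      markers_per_domain=10, seed=7))


@pytest.fixture(scope="session")
def small_ds(small_raw):
    return sdg.preprocess(small_raw)


@pytest.fixture(scope="session")
def small_graph(small_ds):
    return sdg.build_dual_graph(small_ds.coords, small_ds.expr,
                                sdg.GraphConfig(radius=SYN_RADIUS, knn=10))


@pytest.fixture(scope="session")
def bench_runs():
    """Full pipeline on the easy benchmark, five seeds, 100 epochs."""
    runs = []
    for seed in BENCH_SEEDS:
        ds = sdg.easy_benchmark(seed=seed)
        res = sdg.run_pipeline(
            ds, 5,
            graph_cfg=sdg.GraphConfig(radius=SYN_RADIUS, knn=15),
            train_cfg=sdg.TrainConfig(max_epochs=100, seed=seed))
        base = sdg.pca_kmeans_baseline(res.dataset, 5, seed=seed)
        runs.append({
            "history": res.train_result.history,
            "ari": res.ari,
            "baseline_ari": sdg.ari(ds.labels, base),
        })
    return runs


@pytest.fixture(scope="session")
def ablation_aris():
    """Mean ARI of the full model and each single-component ablation.

    All five arms are trained under identical conditions (60-epoch budget,
    same seeds) so the comparison isolates the removed component.
    """
    arms = {
        "full": sdg.AblationFlags(),
        "no_dual_graph": sdg.AblationFlags(dual_graph=False),
        "no_dgi": sdg.AblationFlags(dgi=False),
        "no_consistency": sdg.AblationFlags(consistency=False),
        "no_zinb": sdg.AblationFlags(zinb=False),
    }
    out = {}
    for name, flags in arms.items():
        aris = []
        for seed in BENCH_SEEDS:
            ds = sdg.easy_benchmark(seed=seed)
            res = sdg.run_pipeline(
                ds, 5,
                graph_cfg=sdg.GraphConfig(radius=SYN_RADIUS, knn=15),
                train_cfg=sdg.TrainConfig(max_epochs=60, seed=seed),
                flags=flags)
            aris.append(res.ari)
        out[name] = np.mean(aris)
    return out
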