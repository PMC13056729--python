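"""Readout, discriminator, hard-negative mining, and the DGI objective."""

import numpy as np
import pytest
import scipy.sparse as sp

from spatialdg.autodiff import Tensor
from spatialdg.contrastive import (ContrastState, contrast_projection,
                                   dgi_loss, discriminate,
                                   select_hard_negatives, spatial_bias,
                                   spatial_readout)


def path_graph(n):
    A = sp.lil_matrix((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return sp.csr_matrix(A)


def negatives_oracle(H, A_s, A_f):
    """Exhaustive exclusion-set + argmax scan (ties to the lower index)."""
    n = H.shape[0]
    Hn = H / np.maximum(np.linalg.norm(H, axis=1, keepdims=True), 1e-300)
    S = Hn @ Hn.T
    As, Af = A_s.toarray(), A_f.toarray()
    out = np.full(n, -1)
    for i in range(n):
        excl = {i} | set(np.flatnonzero(As[i])) | set(np.flatnonzero(Af[i]))
        cands = [k for k in range(n) if k not in excl]
        if cands:
            sims = [S[i, k] for k in cands]
            out[i] = cands[int(np.argmax(sims))]
    return out


class TestSpatialReadout:
    def test_edgeless_graph_is_sigmoid_of_column_mean(self):
        rng = np.random.default_rng(0)
        H = rng.normal(size=(6, 4))
        s, w = spatial_readout(Tensor(H), sp.csr_matrix((6, 6)))
        np.testing.assert_array_equal(w, 1.0)
        from scipy.special import expit
        np.testing.assert_allclose(s.data.ravel(), expit(H.mean(axis=0)),
                                   atol=1e-12)

    def test_single_spot(self):
        H = np.array([[0.3, -0.7]])
        s, _ = spatial_readout(Tensor(H), sp.csr_matrix((1, 1)))
        from scipy.special import expit
        np.testing.assert_allclose(s.data.ravel(), expit(H[0]))

    def test_path_graph_degree_weighted_mean(self):
        rng = np.random.default_rng(1)
        H = rng.normal(size=(5, 3))
        s, w = spatial_readout(Tensor(H), path_graph(5))
        np.testing.assert_array_equal(w, [2, 3, 3, 3, 2])
        from scipy.special import expit
        expected = expit((w[:, None] * H).sum(axis=0) / w.sum())
        np.testing.assert_allclose(s.data.ravel(), expected, atol=1e-12)


class TestDiscriminator:
    def test_zero_embedding_zero_bias_gives_half(self):
        out = discriminate(np.zeros(4), np.ones(4), Tensor(0.0),
                           Tensor(np.eye(4)))
        assert out.item() == pytest.approx(0.5)

    def test_identity_bilinear_reduces_to_inner_product(self):
        h = np.array([0.2, -0.4])
        s = np.array([1.0, 0.5])
        from scipy.special import expit
        out = discriminate(h, s, Tensor(0.3), Tensor(np.eye(2)))
        assert out.item() == pytest.approx(expit(h @ s + 0.3))

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            out = discriminate(rng.normal(size=3), rng.normal(size=3),
                               Tensor(rng.normal()),
                               Tensor(rng.normal(size=(3, 3))))
            assert 0.0 < out.item() < 1.0

    def test_spatial_bias_scales_with_degree(self):
        A = path_graph(4)
        b = spatial_bias(A, Tensor(np.array([2.0])))
        # degrees 1,2,2,1 -> scaled by max 2
        np.testing.assert_allclose(b.data.ravel(), [1.0, 2.0, 2.0, 1.0])


class TestHardNegatives:
    def test_singleton_candidate_set(self):
        H = np.array([[1.0, 0], [0, 1.0], [1.0, 1.0]])
        A = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]],
                                   dtype=float))
        empty = sp.csr_matrix((3, 3))
        neg = select_hard_negatives(H, A, empty, rng_seed=0)
        assert neg[0] == 2

    def test_fully_connected_forces_seeded_fallback(self):
        n = 6
        A = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        H = np.random.default_rng(0).normal(size=(n, 3))
        neg1 = select_hard_negatives(H, A, sp.csr_matrix((n, n)), rng_seed=42)
        neg2 = select_hard_negatives(H, A, sp.csr_matrix((n, n)), rng_seed=42)
        np.testing.assert_array_equal(neg1, neg2)
        assert np.all(neg1 != np.arange(n))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        H = rng.normal(size=(n, 8))
        As = sp.random(n, n, density=0.1, random_state=seed, format="csr")
        As = ((As + As.T) != 0).astype(float)
        As.setdiag(0)
        As.eliminate_zeros()
        Af = sp.random(n, n, density=0.05, random_state=seed + 1, format="csr")
        Af = ((Af + Af.T) != 0).astype(float)
        Af.setdiag(0)
        Af.eliminate_zeros()
        neg = select_hard_negatives(H, sp.csr_matrix(As), sp.csr_matrix(Af),
                                    rng_seed=seed)
        oracle = negatives_oracle(H, sp.csr_matrix(As), sp.csr_matrix(Af))
        has_cands = oracle >= 0
        np.testing.assert_array_equal(neg[has_cands], oracle[has_cands])
        # fallback rows: any j != i
        assert np.all(neg[~has_cands] != np.flatnonzero(~has_cands))

    def test_negative_never_in_exclusion_set(self, small_ds, small_graph):
        rng = np.random.default_rng(9)
        H = rng.normal(size=(small_ds.n_spots, 16))
        neg = select_hard_negatives(H, small_graph.A_s, small_graph.A_f, 1)
        E = (small_graph.A_s + small_graph.A_f).toarray() > 0
        for i, j in enumerate(neg):
            assert j != i and not E[i, j]

    def test_requires_two_spots(self):
        with pytest.raises(ValueError):
            select_hard_negatives(np.ones((1, 4)), sp.csr_matrix((1, 1)),
                                  sp.csr_matrix((1, 1)), 0)


class TestDgiLoss:
    def test_degenerate_half_discriminator_gives_two_log_two(self):
        """With all-zero embeddings and bias, D = 0.5 everywhere."""
        n = 8
        H = Tensor(np.zeros((n, 4)))
        s = Tensor(np.full((4, 1), 0.7))
        bias = Tensor(np.zeros((n, 1)))
        W = Tensor(np.eye(4))
        neg = np.roll(np.arange(n), 1)
        loss = dgi_loss(H, neg, s, bias, W, sp.csr_matrix((n, n)),
                        lambda_spatial=0.0)
        assert loss.item() == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_identical_embeddings_zero_spatial_penalty(self):
        n = 5
        H = Tensor(np.ones((n, 3)))
        s = Tensor(np.full((3, 1), 0.5))
        bias = Tensor(np.zeros((n, 1)))
        W = Tensor(np.eye(3))
        neg = np.roll(np.arange(n), 1)
        A = path_graph(n)
        l0 = dgi_loss(H, neg, s, bias, W, A, lambda_spatial=0.0)
        l1 = dgi_loss(H, neg, s, bias, W, A, lambda_spatial=5.0)
        assert l0.item() == pytest.approx(l1.item(), rel=1e-12)

    def test_matches_term_by_term_scalar_oracle(self):
        rng = np.random.default_rng(3)
        n = 4
        H = rng.normal(size=(n, 3))
        W = rng.normal(size=(3, 3))
        sv = rng.normal(size=3)
        bias = rng.normal(size=n)
        neg = np.array([2, 3, 0, 1])
        A = path_graph(n)
        lam = 0.3
        from scipy.special import expit
        pos_terms = [np.log(expit(H[i] @ W @ sv + bias[i])) for i in range(n)]
        neg_terms = [np.log(1 - expit(H[neg[i]] @ W @ sv + bias[i]))
                     for i in range(n)]
        penalty = sum(((H[i] - H[j]) ** 2).sum()
                      for i in range(n) for j in range(i + 1, n)
                      if A[i, j])
        expected = -(np.sum(pos_terms) + np.sum(neg_terms)) / n + lam * penalty
        got = dgi_loss(Tensor(H), neg, Tensor(sv[:, None]),
                       Tensor(bias[:, None]), Tensor(W), A,
                       lambda_spatial=lam)
        assert got.item() == pytest.approx(expected, rel=1e-9)

    def test_loss_nonnegative_without_penalty(self):
        rng = np.random.default_rng(4)
        n = 10
        H = Tensor(rng.normal(size=(n, 4)))
        s = Tensor(rng.normal(size=(4, 1)))
        bias = Tensor(rng.normal(size=(n, 1)))
        W = Tensor(rng.normal(size=(4, 4)))
        neg = np.roll(np.arange(n), 1)
        loss = dgi_loss(H, neg, s, bias, W, sp.csr_matrix((n, n)), 0.0)
        assert loss.item() >= 0.0


class TestContrastProjection:
    def test_identity_mlp_with_nonnegative_input_is_identity(self):
        state = ContrastState.init(3, rng=np.random.default_rng(0))
        state.mlp_W1.data = np.eye(3)
        state.mlp_b1.data = np.zeros(3)
        state.mlp_W2.data = np.eye(3)
        state.mlp_b2.data = np.zeros(3)
        X = np.abs(np.random.default_rng(1).normal(size=(5, 3)))
        out = contrast_projection(Tensor(X), state)
        np.testing.assert_allclose(out.data, X)

    def test_zero_input_returns_output_bias(self):
        state = ContrastState.init(3, rng=np.random.default_rng(2))
        state.mlp_b2.data = np.array([1.0, -2.0, 0.5])
        state.mlp_b1.data = np.zeros(3)
        out = contrast_projection(Tensor(np.zeros((4, 3))), state)
        np.testing.assert_allclose(out.data,
                                   np.tile(state.mlp_b2.data, (4, 1)))

    def test_matches_two_layer_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        state = ContrastState.init(4, rng=rng)
        X = rng.normal(size=(6, 4))
        expected = np.maximum(X @ state.mlp_W1.data + state.mlp_b1.data, 0) \
            @ state.mlp_W2.data + state.mlp_b2.data
        out = contrast_projection(Tensor(X), state)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_trained_discriminator_separates_positives_from_negatives(small_ds,
                                                                  small_graph):
    """After training, D scores true pairs above hard-negative pairs."""
    import spatialdg as sdg
    from spatialdg.contrastive import _discriminate_all
    res = sdg.train(small_ds, small_graph,
                    sdg.TrainConfig(max_epochs=40, seed=0))
    emb = sdg.encode(small_ds.expr, small_graph, res.encoder, mode="eval")
    h = contrast_projection(emb.weighted, res.contrast)
    s, _ = spatial_readout(h, small_graph.A_s)
    bias = spatial_bias(small_graph.A_s, res.contrast.b0)
    neg = select_hard_negatives(h.data, small_graph.A_s, small_graph.A_f, 0)
    pos_scores = _discriminate_all(h, s, bias, res.contrast.W_spatial)
    neg_scores = _discriminate_all(h[neg], s, bias, res.contrast.W_spatial)
    assert pos_scores.data.mean() > neg_scores.data.mean()
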