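import numpy as np
import pytest

from lncdra import (TrainConfig, encode, gat_layer, gcn_encode,
                    gip_similarity, init_params, normalize_adjacency, score)
from lncdra.autodiff import Tensor
from lncdra.errors import ContractError
from lncdra.model import (GATLayerParams, GCNParams, attention_logits,
                          attention_normalize, load_checkpoint,
                          neighborhood_mask, save_checkpoint)
from conftest import random_association


def make_gat_params(rng, d_in, c, K=2, fusion="average", slope=0.2):
    return GATLayerParams(
        W=[Tensor(rng.standard_normal((d_in, c)), requires_grad=True)
           for _ in range(K)],
        a=[Tensor(rng.standard_normal(2 * c), requires_grad=True)
           for _ in range(K)],
        fusion=fusion, leaky_slope=slope)


class TestNormalizeAdjacency:
    def test_single_node(self):
        out = normalize_adjacency(np.array([[1.0]]))
        assert np.allclose(out.A_hat, [[1.0]])

    def test_two_node_hand_oracle(self):
        s = 0.3
        out = normalize_adjacency(np.array([[1.0, s], [s, 1.0]]))
        assert np.allclose(out.A_hat, np.array([[2, s], [s, 2]]) / (2 + s))

    def test_zero_graph_gives_identity(self):
        out = normalize_adjacency(np.zeros((4, 4)))
        assert np.allclose(out.A_hat, np.eye(4))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        M = rng.random((6, 6))
        G = (M + M.T) / 2
        out = normalize_adjacency(G)
        assert np.allclose(out.A_hat, out.A_hat.T, atol=1e-10)


class TestGCNEncode:
    def test_identity_passthrough(self):
        X = np.abs(np.random.default_rng(0).standard_normal((4, 4)))
        params = GCNParams(W0=Tensor(np.eye(4)), W1=Tensor(np.eye(4)),
                           activation_out="identity")
        from lncdra.model import NormalizedAdjacency
        out = gcn_encode(X, NormalizedAdjacency(np.eye(4)), params)
        assert np.allclose(out, X)

    def test_matches_chained_product_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            k = int(rng.integers(2, 8))
            X = rng.standard_normal((k, k))
            W0 = rng.standard_normal((k, 5))
            W1 = rng.standard_normal((5, 3))
            M = rng.random((k, k))
            A_hat = normalize_adjacency((M + M.T) / 2)
            params = GCNParams(W0=Tensor(W0), W1=Tensor(W1),
                               activation_out="identity")
            expected = A_hat.A_hat @ np.maximum(
                A_hat.A_hat @ X @ W0, 0.0) @ W1
            assert np.allclose(gcn_encode(X, A_hat, params), expected,
                               atol=1e-6)

    def test_row_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 5))
        params = GCNParams(W0=Tensor(rng.standard_normal((5, 6))),
                           W1=Tensor(rng.standard_normal((6, 3))),
                           activation_out="row_softmax")
        A_hat = normalize_adjacency(np.abs(rng.random((5, 5))) * 0 + np.eye(5))
        out = gcn_encode(X, A_hat, params)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-8)


class TestAttention:
    def test_zero_attention_vector_zero_logits(self):
        rng = np.random.default_rng(0)
        params = make_gat_params(rng, 3, 2)
        params.a[0] = Tensor(np.zeros(4))
        e = attention_logits(rng.standard_normal((4, 3)), params, head=0)
        assert np.array_equal(e, np.zeros((4, 4)))

    def test_identical_features_constant_logits(self):
        rng = np.random.default_rng(1)
        params = make_gat_params(rng, 3, 2)
        X = np.tile(rng.standard_normal(3), (5, 1))
        e = attention_logits(X, params, head=1)
        assert np.allclose(e, e[0, 0])

    def test_two_node_scalar_hand_computation(self):
        W = np.array([[2.0]])
        a = np.array([1.0, -0.5])
        params = GATLayerParams(W=[Tensor(W)], a=[Tensor(a)], fusion="average")
        X = np.array([[1.0], [3.0]])
        # Wx = (2, 6); e_01 = LeakyReLU(1*2 + (-0.5)*6) = LeakyReLU(-1) = -0.2
        e = attention_logits(X, params, head=0)
        assert e[0, 1] == pytest.approx(-0.2)
        assert e[1, 0] == pytest.approx(6.0 - 1.0)

    def test_single_neighbor_weight_one(self):
        mask = np.eye(3, dtype=bool)
        amap = attention_normalize(np.random.default_rng(0).random((3, 3)),
                                   mask)
        assert np.allclose(np.diag(amap.alpha), 1.0)

    def test_uniform_logits_uniform_weights(self):
        mask = np.ones((4, 4), dtype=bool)
        amap = attention_normalize(np.zeros((4, 4)), mask)
        assert np.allclose(amap.alpha, 0.25)

    def test_closed_form_softmax_pair(self):
        mask = np.array([[True, True]])
        amap = attention_normalize(np.array([[0.0, np.log(2.0)]]), mask)
        assert np.allclose(amap.alpha, [[1 / 3, 2 / 3]])

    def test_empty_neighborhood_rejected(self):
        with pytest.raises(ContractError):
            attention_normalize(np.zeros((2, 2)),
                                np.array([[True, False], [False, False]]))


def brute_force_gat(X, params: GATLayerParams, mask):
    """Per-node, per-head aggregation oracle with explicit loops."""
    k = X.shape[0]
    slope = params.leaky_slope

    def lrelu(v):
        return np.where(v > 0, v, slope * v)

    def elu(v):
        return np.where(v > 0, v, np.exp(v) - 1)

    head_outputs = []
    for W, a in zip(params.W, params.a):
        W, a = W.data, a.data
        c = W.shape[1]
        H = X @ W
        agg = np.zeros((k, c))
        for i in range(k):
            nbrs = np.where(mask[i])[0]
            e = np.array([lrelu(a[:c] @ H[i] + a[c:] @ H[j]) for j in nbrs])
            w = np.exp(e - e.max())
            w = w / w.sum()
            agg[i] = sum(wj * H[j] for wj, j in zip(w, nbrs))
        head_outputs.append(agg)
    if params.fusion == "concat":
        return np.concatenate([elu(h) for h in head_outputs], axis=1)
    return elu(np.mean(head_outputs, axis=0))


class TestGATLayer:
    def test_isolated_node_identity(self):
        params = GATLayerParams(W=[Tensor(np.eye(2))],
                                a=[Tensor(np.zeros(4))], fusion="average")
        X = np.array([[0.7, 0.2]])
        out = gat_layer(X, np.array([[1.0]]), params)
        assert np.allclose(out, X)  # ELU is identity on positives

    def test_concat_width_is_heads_times_c(self):
        rng = np.random.default_rng(2)
        params = make_gat_params(rng, 4, 25, K=8, fusion="concat")
        m = random_association(rng, 6, 3)
        G = gip_similarity(m, "lncrna")
        out = gat_layer(rng.standard_normal((6, 4)), G, params)
        assert out.shape == (6, 200)

    @pytest.mark.parametrize("fusion", ["concat", "average"])
    def test_matches_bruteforce_oracle(self, fusion):
        rng = np.random.default_rng(9)
        for _ in range(10):
            k = int(rng.integers(2, 8))
            params = make_gat_params(rng, 3, 4, K=3, fusion=fusion)
            X = rng.standard_normal((k, 3))
            m = random_association(rng, k, 4)
            G = gip_similarity(m, "lncrna")
            mask = neighborhood_mask(G, None)
            assert np.allclose(gat_layer(X, G, params),
                               brute_force_gat(X, params, mask), atol=1e-6)

    def test_knn_mask_tie_break_smaller_index(self):
        G = np.array([[1.0, 0.5, 0.5, 0.1],
                      [0.5, 1.0, 0.2, 0.2],
                      [0.5, 0.2, 1.0, 0.2],
                      [0.1, 0.2, 0.2, 1.0]])
        mask = neighborhood_mask(G, knn=2)
        # node 3 ties between nodes 1 and 2 (0.2 each): keep smaller index
        assert mask[3, 1] and not mask[3, 2]
        assert mask[3, 3]  # self always kept


class TestEncodeAndScore:
    def test_default_embedding_width_200(self):
        rng = np.random.default_rng(0)
        m = random_association(rng, 12, 6, density=0.5)
        config = TrainConfig(epochs=0, knn=None)
        params = init_params(m.m, m.n, config)
        Xl, Xd = encode(m, config, params)
        assert Xl.shape == (12, 200) and Xd.shape == (6, 200)
        assert np.isfinite(Xl).all() and np.isfinite(Xd).all()

    def test_variants_share_similarity_and_shapes(self):
        rng = np.random.default_rng(1)
        m = random_association(rng, 10, 4, density=0.5)
        for variant in ("full", "gcn_only", "gat_only"):
            config = TrainConfig(epochs=0, variant=variant, embedding_size=8,
                                 gcn_hidden=6, heads=2, knn=None)
            params = init_params(m.m, m.n, config)
            Xl, Xd = encode(m, config, params)
            assert Xl.shape == (10, 8) and Xd.shape == (4, 8)

    def test_node_relabeling_equivariance(self):
        rng = np.random.default_rng(6)
        m = random_association(rng, 8, 5, density=0.5)
        config = TrainConfig(epochs=0, embedding_size=6, gcn_hidden=4,
                             heads=2, knn=None, variant="gat_only")
        params = init_params(m.m, m.n, config)
        G = gip_similarity(m, "lncrna")
        layer = params.lnc.gat_layers[0]
        out = gat_layer(G.G, G, layer)
        perm = rng.permutation(8)
        # permute node rows (features stay in the same columns); the
        # neighborhood is the full graph so the mask is permutation-stable
        out_p = gat_layer(G.G[perm], G, layer)
        assert np.allclose(out_p, out[perm], atol=1e-8)

    def test_zero_embeddings_score_half(self):
        assert np.allclose(score(np.zeros((3, 4)), np.zeros((2, 4))), 0.5)

    def test_log3_product_scores_three_quarters(self):
        s = score(np.array([[np.log(3.0)]]), np.array([[1.0]]))
        assert s[0, 0] == pytest.approx(0.75)

    def test_matches_pairwise_dot_oracle(self):
        rng = np.random.default_rng(4)
        Xl, Xd = rng.standard_normal((5, 7)), rng.standard_normal((3, 7))
        S = score(Xl, Xd)
        for i in range(5):
            for j in range(3):
                expected = 1 / (1 + np.exp(-np.dot(Xl[i], Xd[j])))
                assert S[i, j] == pytest.approx(expected, abs=1e-10)

    def test_score_antisymmetry_under_negation(self):
        rng = np.random.default_rng(5)
        Xl, Xd = rng.standard_normal((4, 3)), rng.standard_normal((2, 3))
        assert np.allclose(score(-Xl, Xd), 1 - score(Xl, Xd))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ContractError):
            score(np.zeros((2, 3)), np.zeros((2, 4)))


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    m = random_association(rng, 6, 4, density=0.5)
    config = TrainConfig(epochs=0, embedding_size=4, gcn_hidden=3, heads=2)
    params = init_params(m.m, m.n, config)
    path = tmp_path / "ckpt.json"
    save_checkpoint(str(path), params, config, m)
    params2, config2, lnc_ids, drug_ids = load_checkpoint(str(path))
    assert lnc_ids == m.lnc_ids and drug_ids == m.drug_ids
    Xl1, Xd1 = encode(m, config, params)
    Xl2, Xd2 = encode(m, config2, params2)
    assert np.allclose(Xl1, Xl2) and np.allclose(Xd1, Xd2)
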