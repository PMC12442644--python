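import numpy as np
import pytest
import scipy.sparse as sp

from sgcd.graph import WeightedGraph, normalize_adjacency
from sgcd.model import (
    ModelConfig,
    ModelState,
    _forward_backward,
    context_matrix,
    context_vectors,
    decode,
    discriminate,
    encode,
    gcn_layer,
    recon_loss,
    scl_loss,
    scl_loss_random,
    total_loss,
    train,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def path_graph(n, weights=None):
    edges = [[i, i + 1] for i in range(n - 1)]
    w = np.ones(n - 1) if weights is None else np.asarray(weights, float)
    return WeightedGraph(n_nodes=n, edges=edges, weights=w, gamma=0.2, K=1)


def state_for(n_genes, latent, seed=0, **kw):
    return ModelState.init(n_genes, ModelConfig(latent_dim=latent, seed=seed, **kw))


class TestGcnLayer:
    def test_zero_weights_zero_output(self):
        A = sp.identity(3, format="csr")
        Z = np.random.default_rng(0).normal(size=(3, 4))
        out = gcn_layer(A, Z, np.zeros((4, 2)), np.zeros(2), "relu")
        np.testing.assert_array_equal(out, np.zeros((3, 2)))

    def test_identity_adjacency_is_affine_map(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(3, 4))
        W = rng.normal(size=(4, 2))
        b = rng.normal(size=2)
        out = gcn_layer(sp.identity(3, format="csr"), Z, W, b, "identity")
        np.testing.assert_allclose(out, Z @ W + b)

    def test_two_node_path_hand_arithmetic(self):
        # normalized path graph without self-loops: A = [[0,1],[1,0]]
        A = normalize_adjacency(path_graph(2), self_loops=False).matrix
        Z = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[1.0, 0.0], [0.0, -1.0]])
        b = np.array([0.5, 0.5])
        out = gcn_layer(A, Z, W, b, "identity")
        # A swaps rows; Z @ W negates column 2
        np.testing.assert_allclose(out, [[3.5, -3.5], [1.5, -1.5]])

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(sp.identity(3), np.ones((3, 4)), np.ones((5, 2)),
                      np.zeros(2))


class TestEncodeDecode:
    def test_identity_everything_is_relu(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 3))
        state = state_for(3, 3)
        state.W_e = np.eye(3)
        state.b_e = np.zeros(3)
        Z = encode(sp.identity(4, format="csr"), X, state)
        np.testing.assert_allclose(Z, np.maximum(X, 0))

    def test_decode_restores_gene_dimension(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 7))
        G = path_graph(5)
        A = normalize_adjacency(G).matrix
        state = state_for(7, 3)
        Z = encode(A, X, state)
        H = decode(A, Z, state)
        assert Z.shape == (5, 3)
        assert H.shape == X.shape


class TestReconLoss:
    def test_identical_is_zero(self):
        X = np.random.default_rng(0).normal(size=(3, 4))
        assert recon_loss(X, X) == 0.0

    def test_single_entry_difference(self):
        X = np.zeros((2, 3))
        H = np.zeros((2, 3))
        H[1, 2] = 2.0
        assert recon_loss(X, H) == 4.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(3, 4))
        H = rng.normal(size=(3, 4))
        oracle = sum((X[i, j] - H[i, j]) ** 2
                     for i in range(3) for j in range(4))
        assert recon_loss(X, H) == pytest.approx(oracle, rel=1e-12)


class TestContextVectors:
    def test_uniform_embeddings_give_sigmoid_z(self):
        z = np.array([0.3, -1.2, 2.0])
        Z = np.tile(z, (4, 1))
        G = path_graph(4)
        g = context_vectors(G, Z)
        np.testing.assert_allclose(g, np.tile(sigmoid(z), (4, 1)), atol=1e-12)

    def test_isolated_node_gets_half(self):
        G = WeightedGraph(n_nodes=3, edges=[[0, 1]], weights=[1.0],
                          gamma=0.2, K=1)
        g = context_vectors(G, np.random.default_rng(0).normal(size=(3, 2)))
        np.testing.assert_allclose(g[2], [0.5, 0.5])

    def test_star_hand_computation(self):
        # node 0 linked to 1 and 2 with weights 0.3 and 0.7
        G = WeightedGraph(n_nodes=3, edges=[[0, 1], [0, 2]],
                          weights=[0.3, 0.7], gamma=0.2, K=2)
        Z = np.array([[9.0, 9.0], [1.0, 0.0], [0.0, 1.0]])
        g = context_vectors(G, Z)
        expected0 = sigmoid((0.3 * Z[1] + 0.7 * Z[2]) / 1.0)
        np.testing.assert_allclose(g[0], expected0, atol=1e-12)


class TestDiscriminator:
    def test_zero_bilinear_gives_half(self):
        state = state_for(4, 3)
        state.B = np.zeros((3, 3))
        assert discriminate(np.ones(3), np.ones(3), state) == 0.5

    def test_identity_bilinear_basis_vectors(self):
        state = state_for(4, 3)
        state.B = np.eye(3)
        e1 = np.array([1.0, 0.0, 0.0])
        assert discriminate(e1, e1, state) == pytest.approx(sigmoid(1.0))

    def test_output_in_open_unit_interval(self):
        rng = np.random.default_rng(4)
        state = state_for(4, 3)
        for _ in range(20):
            p = discriminate(rng.normal(size=3) * 10, rng.normal(size=3) * 10,
                             state)
            assert 0.0 < p < 1.0


class TestContrastiveLosses:
    def test_half_probability_gives_ln2(self):
        state = state_for(4, 3)
        state.B = np.zeros((3, 3))  # every score 0 -> Phi = 0.5
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(5, 3))
        Zc = rng.normal(size=(5, 3))
        g = rng.uniform(size=(5, 3))
        assert scl_loss(Z, Zc, g, state) == pytest.approx(np.log(2), abs=1e-12)
        assert scl_loss_random(Z, Zc, g, state) == pytest.approx(np.log(2), abs=1e-12)

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(1)
        state = state_for(4, 3, seed=1)
        Z, Zc, g = (rng.normal(size=(6, 3)) for _ in range(3))
        assert scl_loss_random(Z, Zc, g, state) == pytest.approx(
            scl_loss(Zc, Z, g, state), rel=1e-12)

    def test_matches_per_node_loop_oracle(self):
        rng = np.random.default_rng(2)
        state = state_for(4, 3, seed=2)
        Z, Zc, g = (rng.normal(size=(5, 3)) for _ in range(3))
        n = 5
        oracle = -sum(
            np.log(discriminate(Z[i], g[i], state))
            + np.log(1.0 - discriminate(Zc[i], g[i], state))
            for i in range(n)
        ) / (2 * n)
        assert scl_loss(Z, Zc, g, state) == pytest.approx(oracle, rel=1e-9)

    def test_perfect_discrimination_limit(self):
        state = state_for(4, 1)
        state.B = np.array([[50.0]])
        Z = np.ones((4, 1))
        Zc = -np.ones((4, 1))
        g = np.ones((4, 1))
        assert scl_loss(Z, Zc, g, state) < 1e-9


class TestTotalLoss:
    def test_zero_components(self):
        assert total_loss(0.0, 0.0, 0.0) == 0.0

    def test_default_weighting_arithmetic(self):
        assert total_loss(1.0, 1.0, 1.0) == 12.0

    def test_lambda2_zero_reduces_to_reconstruction(self):
        assert total_loss(3.0, 9.9, 9.9, lambda1=10.0, lambda2=0.0) == 30.0

    def test_linear_in_components(self):
        assert total_loss(2.0, 1.0, 3.0, 5.0, 2.0) == pytest.approx(
            5.0 * 2.0 + 2.0 * (1.0 + 3.0))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        # 4-node fixture, all loss branches active, fixed permutation
        rng = np.random.default_rng(0)
        n, d, h = 4, 5, 3
        X = rng.normal(size=(n, d))
        Xc = X[rng.permutation(n)]
        G = path_graph(n, weights=[0.5, 1.0, 0.7])
        A = normalize_adjacency(G).matrix
        M = context_matrix(G)
        state = state_for(d, h)
        params = state.params()
        _, grads, _, _ = _forward_backward(params, X, Xc, A, M, 10.0, 1.0)

        def loss_at(p):
            losses, _, _, _ = _forward_backward(p, X, Xc, A, M, 10.0, 1.0)
            return losses["total"]

        eps = 1e-6
        for key in params:
            flat = params[key].reshape(-1)
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at(params)
                flat[idx] = orig - eps
                down = loss_at(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, abs=1e-4, rel=1e-4), key


class TestTraining:
    def _fixture(self, n=30, d=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        X[: n // 2] += 2.0
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        from sgcd.graph import knn_edges, weight_edges
        from sgcd.proportions import ProportionMatrix

        A = knn_edges(coords, K=2)
        props = ProportionMatrix(
            values=rng.dirichlet(np.ones(3), size=n),
            spot_ids=[f"s{i}" for i in range(n)],
            type_names=["a", "b", "c"])
        return X, weight_edges(A, props)

    def test_same_seed_bit_identical_traces(self):
        X, G = self._fixture()
        cfg = ModelConfig(latent_dim=6, epochs=25, seed=3)
        r1 = train(X, G, cfg)
        r2 = train(X, G, cfg)
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)
        np.testing.assert_array_equal(r1.Z, r2.Z)

    def test_loss_decreases_over_training(self):
        X, G = self._fixture()
        res = train(X, G, ModelConfig(latent_dim=6, epochs=80, seed=0))
        assert res.loss_trace[-20:].mean() < res.loss_trace[:20].mean()

    def test_loss_trace_length_and_finiteness(self):
        X, G = self._fixture()
        res = train(X, G, ModelConfig(latent_dim=6, epochs=15, seed=0))
        assert len(res.loss_trace) == 15
        assert np.all(np.isfinite(res.loss_trace))
        assert np.all(np.isfinite(res.Z)) and np.all(np.isfinite(res.H))

    def test_reconstruction_bounded_by_svd_oracle(self):
        # with an edgeless graph (A_norm = I) the decoder output is an
        # affine rank-h map of X, so the squared error cannot beat the
        # truncated-SVD bound on the centered matrix
        rng = np.random.default_rng(1)
        n, d, h = 20, 8, 3
        X = rng.normal(size=(n, d))
        G = WeightedGraph(n_nodes=n, edges=np.empty((0, 2)), weights=[],
                          gamma=0.2, K=0)
        res = train(X, G, ModelConfig(latent_dim=h, epochs=300,
                                      learning_rate=1e-2, seed=0, lambda2=0.0))
        final_recon = recon_loss(X, res.H)
        Xc = X - X.mean(axis=0)
        svals = np.linalg.svd(Xc, compute_uv=False)
        bound = (svals[h:] ** 2).sum()
        assert final_recon >= bound - 1e-6

    def test_ablation_flags_recorded_in_state(self):
        X, G = self._fixture()
        res = train(X, G, ModelConfig(latent_dim=4, epochs=5, seed=0,
                                      lambda1=0.0))
        assert res.state.config.lambda1 == 0.0
        np.testing.assert_allclose(res.loss_components["recon"] * 0.0, 0.0)
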