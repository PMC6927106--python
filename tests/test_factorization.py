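"""Multiplicative-update solver: Laplacians, objective, updates,
convergence and variant configuration."""

import numpy as np
import pytest

from hpofactor.containers import EntityIndex, SimilarityNetwork
from hpofactor.factorization import (
    ConfigurationError,
    Hyperparams,
    fit,
    graph_laplacian,
    grid_search,
    kkt_residual,
    objective,
    predict,
    split_laplacian,
    update_U,
    update_V,
    variant_config,
)


def _net(W):
    W = np.asarray(W, float)
    ids = [f"n{i}" for i in range(W.shape[0])]
    return SimilarityNetwork(weights=W, index=EntityIndex.from_ids(ids))


def _random_net(n, rng, density=0.5):
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestLaplacian:
    def test_two_node_graph(self):
        L = graph_laplacian(_net([[0, 1], [1, 0]]))
        assert np.array_equal(L, [[1, -1], [-1, 1]])

    def test_disconnected_node_zero_row(self):
        L = graph_laplacian(_net([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        assert np.all(L[2] == 0) and np.all(L[:, 2] == 0)

    def test_quadratic_form_identity(self):
        # x^T L x = 1/2 sum_ij S_ij (x_i - x_j)^2
        rng = np.random.default_rng(5)
        S = _random_net(5, rng)
        L = graph_laplacian(S)
        for _ in range(5):
            x = rng.normal(size=5)
            brute = 0.5 * sum(
                S[i, j] * (x[i] - x[j]) ** 2 for i in range(5) for j in range(5)
            )
            assert x @ L @ x == pytest.approx(brute, abs=1e-10)


class TestSplitLaplacian:
    def test_two_node_split(self):
        pair = split_laplacian(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert np.array_equal(pair.plus, np.eye(2))
        assert np.array_equal(pair.minus, [[0, 1], [1, 0]])

    def test_nonnegative_matrix_has_zero_minus(self):
        pair = split_laplacian(np.array([[1.0, 2.0], [0.0, 3.0]]))
        assert np.all(pair.minus == 0)

    def test_reconstruction_exact_random(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(6, 6))
        pair = split_laplacian(L)
        assert np.array_equal(pair.plus - pair.minus, L)
        assert np.all(pair.plus >= 0) and np.all(pair.minus >= 0)


class TestObjective:
    def test_zero_factors_give_squared_norm(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        h = Hyperparams(K=2, lam=0.0)
        J = objective(np.zeros((2, 2)), np.zeros((2, 2)), Y, None, None, [], h)
        assert J == pytest.approx((Y**2).sum())

    def test_exact_factorization_zero(self):
        rng = np.random.default_rng(1)
        U, V = rng.random((4, 2)), rng.random((3, 2))
        h = Hyperparams(K=2, lam=0.0)
        assert objective(U, V, U @ V.T, None, None, [], h) == pytest.approx(0.0)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(2)
        n_p, n_h, K = 4, 3, 2
        U, V = rng.random((n_p, K)), rng.random((n_h, K))
        Y = (rng.random((n_p, n_h)) < 0.5).astype(float)
        W = (rng.random((n_p, n_h)) < 0.8).astype(float)
        Sp, Sh = _random_net(n_p, rng), _random_net(n_h, rng)
        Lp, Lh = graph_laplacian(Sp), graph_laplacian(Sh)
        h = Hyperparams(K=K, lam=0.3, alpha=0.7, beta=0.2)

        J_loop = 0.0
        for i in range(n_p):
            for j in range(n_h):
                pred = sum(U[i, k] * V[j, k] for k in range(K))
                J_loop += (W[i, j] * (Y[i, j] - pred)) ** 2
        J_loop += h.lam * (sum(u * u for u in U.ravel()) + sum(v * v for v in V.ravel()))
        for k in range(K):
            J_loop += h.alpha * float(U[:, k] @ Lp @ U[:, k])
            J_loop += h.beta * float(V[:, k] @ Lh @ V[:, k])
        assert objective(U, V, Y, W, Lh, [Lp], h) == pytest.approx(J_loop, abs=1e-10)

    def test_shape_mismatch_is_hard_error(self):
        h = Hyperparams(K=2)
        with pytest.raises(ValueError):
            objective(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros((2, 2)), None, None, [], h)


class TestUpdates:
    def test_scalar_update_hand_value(self):
        # V' = 0.5 * sqrt(1 / 0.5) = sqrt(0.5)
        h = Hyperparams(K=1, lam=0.0)
        V = update_V(
            np.array([[1.0]]), np.array([[0.5]]), np.array([[1.0]]),
            np.array([[1.0]]), None, h,
        )
        assert V[0, 0] == pytest.approx(np.sqrt(0.5), rel=1e-9)

    def test_fixed_point_stays(self):
        h = Hyperparams(K=1, lam=0.0)
        V = update_V(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]]),
            np.array([[1.0]]), None, h,
        )
        assert V[0, 0] == pytest.approx(1.0, rel=1e-9)

    def test_zero_entries_stay_zero(self):
        rng = np.random.default_rng(3)
        U = rng.random((4, 2))
        V = rng.random((3, 2))
        V[1, :] = 0.0
        Y = (rng.random((4, 3)) < 0.5).astype(float)
        h = Hyperparams(K=2, lam=0.1)
        V2 = update_V(U, V, Y, None, None, h)
        assert np.all(V2[1, :] == 0.0)

    def test_beta_zero_matches_plain_masked_update(self):
        rng = np.random.default_rng(4)
        U, V = rng.random((4, 2)), rng.random((3, 2))
        Y = (rng.random((4, 3)) < 0.5).astype(float)
        W = (rng.random((4, 3)) < 0.7).astype(float)
        h = Hyperparams(K=2, lam=0.2, beta=0.0)
        got = update_V(U, V, Y, W, split_laplacian(graph_laplacian(_random_net(3, rng))), h)
        # independent re-implementation without the Laplacian terms
        num = (W * Y).T @ U
        den = (W * (U @ V.T)).T @ U + h.lam * V
        want = V * np.sqrt(num / (den + 1e-12))
        assert np.allclose(got, want, atol=1e-12)

    def test_two_identical_ppns_equal_doubled_alpha(self):
        rng = np.random.default_rng(5)
        U, V = rng.random((5, 2)), rng.random((4, 2))
        Y = (rng.random((5, 4)) < 0.5).astype(float)
        Sp = _random_net(5, rng)
        pair = split_laplacian(graph_laplacian(Sp))
        h1 = Hyperparams(K=2, lam=0.1, alpha=0.6)
        h2 = Hyperparams(K=2, lam=0.1, alpha=1.2)
        twice = update_U(U, V, Y, None, [pair, pair], h1)
        doubled = update_U(U, V, Y, None, [pair], h2)
        assert np.allclose(twice, doubled, atol=1e-12)

    def test_nonnegativity_and_monotonicity_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n_p, n_h, K = (int(rng.integers(2, 7)) for _ in range(3))
            K = max(1, min(K, 3))
            Y = (rng.random((n_p, n_h)) < 0.4).astype(float)
            W = (rng.random((n_p, n_h)) < 0.8).astype(float)
            Sp, Sh = _random_net(n_p, rng), _random_net(n_h, rng)
            Lp, Lh = graph_laplacian(Sp), graph_laplacian(Sh)
            pairs_p, pair_h = [split_laplacian(Lp)], split_laplacian(Lh)
            h = Hyperparams(K=K, lam=0.2, alpha=0.3, beta=0.3)
            U = rng.random((n_p, K))
            V = rng.random((n_h, K))
            J = objective(U, V, Y, W, Lh, [Lp], h)
            for _ in range(5):
                U = update_U(U, V, Y, W, pairs_p, h)
                V = update_V(U, V, Y, W, pair_h, h)
                J_new = objective(U, V, Y, W, Lh, [Lp], h)
                assert np.all(U >= 0) and np.all(V >= 0)
                assert J_new <= J * (1 + 1e-9) + 1e-12
                J = J_new


class TestFit:
    def test_recovers_planted_rank_two(self):
        rng = np.random.default_rng(7)
        U_true, V_true = rng.random((20, 2)), rng.random((15, 2))
        Y = U_true @ V_true.T
        h = Hyperparams(K=2, lam=1e-6, max_iter=3000, tol=1e-12, seed=0)
        model = fit(Y, None, None, [], h)
        rel = np.linalg.norm(Y - predict(model)) / np.linalg.norm(Y)
        assert rel < 1e-3

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(8)
        Y = (rng.random((10, 8)) < 0.3).astype(float)
        h = Hyperparams(K=3, lam=0.1, max_iter=100, tol=1e-12, seed=1)
        model = fit(Y, None, None, [], h)
        tr = np.array(model.objective_trace)
        assert np.all(np.diff(tr) <= tr[:-1] * 1e-9 + 1e-12)

    def test_missing_networks_with_positive_coefficients_is_error(self):
        Y = np.ones((3, 3))
        with pytest.raises(ConfigurationError):
            fit(Y, None, None, [], Hyperparams(K=2, alpha=1.0))
        with pytest.raises(ConfigurationError):
            fit(Y, None, None, [], Hyperparams(K=2, beta=1.0))

    def test_empty_matrix_is_hard_error(self):
        with pytest.raises(ValueError):
            fit(np.zeros((0, 0)), None, None, [], Hyperparams(K=1))

    def test_kkt_residual_small_at_tight_convergence(self):
        rng = np.random.default_rng(9)
        Y = (rng.random((6, 5)) < 0.4).astype(float)
        Sp, Sh = _random_net(6, rng), _random_net(5, rng)
        nets_p = [SimilarityNetwork(weights=Sp, index=EntityIndex.from_ids([f"p{i}" for i in range(6)]))]
        net_h = SimilarityNetwork(weights=Sh, index=EntityIndex.from_ids([f"t{i}" for i in range(5)]), kind="term")
        h = Hyperparams(K=2, lam=0.1, alpha=0.2, beta=0.2, max_iter=20000, tol=1e-14, seed=2)
        model = fit(Y, None, net_h, nets_p, h)
        res = kkt_residual(
            model.U, model.V, Y, None,
            graph_laplacian(net_h), [graph_laplacian(nets_p[0])], h,
        )
        assert res < 1e-4

    def test_gradient_matches_numerical_differentiation(self):
        rng = np.random.default_rng(10)
        n_p, n_h, K = 4, 3, 2
        Y = (rng.random((n_p, n_h)) < 0.5).astype(float)
        W = (rng.random((n_p, n_h)) < 0.8).astype(float)
        Lp = graph_laplacian(_random_net(n_p, rng))
        Lh = graph_laplacian(_random_net(n_h, rng))
        h = Hyperparams(K=K, lam=0.3, alpha=0.4, beta=0.5)
        U, V = rng.random((n_p, K)) + 0.1, rng.random((n_h, K)) + 0.1

        WY, WUVt = W * Y, W * (U @ V.T)
        grad_V = 2 * (WUVt.T @ U - WY.T @ U + h.lam * V + h.beta * (Lh @ V))
        grad_U = 2 * (WUVt @ V - WY @ V + h.lam * U + h.alpha * (Lp @ U))

        eps = 1e-6
        for arr, grad, which in ((U, grad_U, "U"), (V, grad_V, "V")):
            num = np.zeros_like(arr)
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + eps
                Jp = objective(U, V, Y, W, Lh, [Lp], h)
                arr[idx] = orig - eps
                Jm = objective(U, V, Y, W, Lh, [Lp], h)
                arr[idx] = orig
                num[idx] = (Jp - Jm) / (2 * eps)
            assert np.allclose(grad, num, atol=1e-5), which

    def test_predict_nonnegative_and_zero_model(self):
        h = Hyperparams(K=2)
        from hpofactor.factorization import FactorModel

        m = FactorModel(U=np.zeros((3, 2)), V=np.ones((4, 2)), hyper=h)
        assert np.all(predict(m) == 0)

    def test_regularization_pulls_connected_proteins_together(self):
        # two connected proteins: ||U_1 - U_2|| shrinks as alpha grows
        rng = np.random.default_rng(11)
        Y = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        Sp = SimilarityNetwork(
            weights=np.array([[0.0, 1.0], [1.0, 0.0]]),
            index=EntityIndex.from_ids(["p0", "p1"]),
        )
        gaps = []
        for alpha in (0.0, 0.5, 2.0, 8.0):
            h = Hyperparams(K=2, lam=0.01, alpha=alpha, max_iter=2000, tol=1e-12, seed=3)
            m = fit(Y, None, None, [Sp] if alpha > 0 else [], h)
            gaps.append(np.linalg.norm(m.U[0] - m.U[1]))
        assert all(b <= a + 1e-9 for a, b in zip(gaps, gaps[1:]))


class TestVariants:
    H = Hyperparams(K=4, lam=0.5, alpha=1.0, beta=1.0)

    def test_nmf_forces_zero_coefficients(self):
        h = variant_config("NMF", self.H, n_ppns=0, has_term_network=False)
        assert h.alpha == 0.0 and h.beta == 0.0

    def test_aipa_rejects_two_networks(self):
        with pytest.raises(ConfigurationError):
            variant_config("AiPA", self.H, n_ppns=2, has_term_network=True)

    def test_hpoannotator_accepts_four_networks(self):
        h = variant_config("HPOAnnotator", self.H, n_ppns=4, has_term_network=True)
        assert h.alpha > 0 and h.beta > 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            variant_config("NOPE", self.H, 1, True)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(12)
        Y = (rng.random((10, 8)) < 0.4).astype(float)
        h = Hyperparams(K=2, lam=0.1, max_iter=50, tol=1e-8, seed=0)
        assert grid_search(Y, None, None, [], [h], folds=3, seed=0) == h

    def test_planted_rank_preferred_over_underfit(self):
        # rank-3 planted data: K=3 should beat K=1 in >= 4/5 seeds
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            U_t, V_t = rng.random((30, 3)), rng.random((20, 3))
            Y = ((U_t @ V_t.T) > np.quantile(U_t @ V_t.T, 0.7)).astype(float)
            good = Hyperparams(K=3, lam=0.1, max_iter=150, tol=1e-8, seed=seed)
            bad = Hyperparams(K=1, lam=0.1, max_iter=150, tol=1e-8, seed=seed)
            best = grid_search(Y, None, None, [], [bad, good], folds=5, seed=seed)
            wins += best == good
        assert wins >= 4
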