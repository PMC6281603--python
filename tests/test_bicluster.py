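"""Convex biclustering: weights, solver, validation path, cluster extraction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from spatialeqtl.bicluster import (
    build_weights,
    cobra_objective,
    cobra_solve,
    extract_clusters,
    gamma_grid,
    validate_path,
)


def planted_share_matrix(n_clusters=3, size=4, within=4 / 7):
    """Block sharing matrix: clusters interleaved round-robin, diagonal 1."""
    n = n_clusters * size
    X = np.zeros((n, n))
    for b in range(n_clusters):
        idx = np.arange(b, n, n_clusters)
        X[np.ix_(idx, idx)] = within
    np.fill_diagonal(X, 1.0)
    return X


class TestWeights:
    def test_identical_columns_get_maximal_weight(self):
        # kernel of a zero distance is exp(0) = 1, the maximal raw weight
        X = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]])
        W = build_weights(X, k=2, phi=0.5)
        edge_w = {tuple(e): w for e, w in zip(W.col_edges, W.col_weights)}
        raw = {
            (i, j): np.exp(-0.5 * np.sum((X[:, i] - X[:, j]) ** 2))
            for i, j in [(0, 1), (0, 2), (1, 2)]
        }
        total = sum(raw.values())
        assert edge_w[(0, 1)] == max(edge_w.values())
        assert edge_w[(0, 1)] == pytest.approx(1.0 / total, rel=1e-9)

    def test_large_k_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 5))
        W = build_weights(X, k=4, phi=0.5)
        assert len(W.col_edges) == 5 * 4 // 2
        assert len(W.row_edges) == 4 * 3 // 2

    def test_knn_edges_match_brute_force(self):
        # 3 columns with pairwise squared distances 1, 2, 3; k=1
        X = np.array([[0.0, 1.0, 1.0 + np.sqrt(2)]])
        D2 = (X.T - X) ** 2
        W = build_weights(np.vstack([X, np.zeros_like(X)]), k=1, phi=0.5)
        edges = {tuple(e) for e in W.col_edges}
        # brute-force 1-NN: 0->1, 1->0, 2->1; union = {(0,1),(1,2)}
        assert edges == {(0, 1), (1, 2)}

    def test_disconnected_graph_escalates_k(self):
        # two tight, far-apart column groups; k=1 keeps them separate
        X = np.array([[0.0, 0.01, 100.0, 100.01]])
        X = np.vstack([X, X])
        with pytest.warns(UserWarning, match="escalating"):
            W = build_weights(X, k=1, phi=0.001)
        edges = {tuple(e) for e in W.col_edges}
        assert (1, 2) in edges  # bridge created

    def test_non_finite_errors(self):
        with pytest.raises(ValueError):
            build_weights(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestGammaGrid:
    def test_default_endpoints(self):
        g = gamma_grid()
        assert g[0] == pytest.approx(1.0)
        assert g[-1] == pytest.approx(1000.0)
        assert len(g) == 100

    def test_log_spacing_second_value(self):
        g = gamma_grid(n=100)
        assert g[1] == pytest.approx(10 ** (3 / 99), rel=1e-12)

    def test_two_point_grid(self):
        assert gamma_grid(n=2) == pytest.approx([1.0, 1000.0])

    def test_linear_option(self):
        g = gamma_grid(n=3, log=False)
        assert g == pytest.approx([1.0, 500.5, 1000.0])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            gamma_grid(low=0.0)
        with pytest.raises(ValueError):
            gamma_grid(n=1)


class TestSolver:
    def test_gamma_zero_returns_input(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 5))
        W = build_weights(X, k=3)
        U, info = cobra_solve(X, W, 0.0)
        assert np.array_equal(U, X)
        assert info["converged"]

    def test_huge_gamma_fuses_to_grand_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 6))
        W = build_weights(X, k=5)
        U, _ = cobra_solve(X, W, 1e6, tol=1e-12, max_iter=2000)
        assert np.abs(U - X.mean()).max() < 1e-3

    def test_objective_monotone_along_grid(self):
        X = planted_share_matrix()
        W = build_weights(X)
        for gamma in gamma_grid(n=10):
            _, info = cobra_solve(X, W, gamma)
            h = np.array(info["objective_history"])
            viol = np.diff(h) / np.maximum(np.abs(h[:-1]), 1.0)
            assert viol.max() <= 1e-8  # descent up to floating-point noise

    def test_matches_generic_convex_oracle(self):
        """Objective at the solution within 1e-4 of scipy L-BFGS on the
        eps-smoothed objective, on small random instances."""
        rng = np.random.default_rng(0)
        for _ in range(8):
            p, m = int(rng.integers(4, 7)), int(rng.integers(4, 7))
            X = rng.normal(size=(p, m))
            W = build_weights(X, k=3)
            gamma = float(10 ** rng.uniform(-1, 1.5))
            _, info = cobra_solve(X, W, gamma, tol=1e-10, max_iter=2000)
            res = minimize(
                lambda u: cobra_objective(X, u.reshape(p, m), W, gamma, 1e-9),
                X.ravel(),
                method="L-BFGS-B",
                options=dict(maxiter=20000, ftol=1e-18, gtol=1e-14),
            )
            f_oracle = cobra_objective(X, res.x.reshape(p, m), W, gamma, 0.0)
            assert info["objective"] <= f_oracle + 1e-4

    def test_negative_gamma_errors(self):
        X = planted_share_matrix()
        with pytest.raises(ValueError):
            cobra_solve(X, build_weights(X), -1.0)


class TestValidation:
    def test_constant_matrix_zero_error(self):
        X = np.full((6, 6), 3.0)
        W = build_weights(X + np.random.default_rng(0).normal(0, 1e-9, X.shape))
        res = validate_path(X, grid=gamma_grid(n=5), weights=W, seed=0)
        # imputation equals the truth and U = X, up to solver smoothing noise
        assert np.allclose(res.errors, 0.0, atol=1e-9)

    def test_deterministic_given_seed(self):
        X = planted_share_matrix()
        r1 = validate_path(X, grid=gamma_grid(n=10), seed=4)
        r2 = validate_path(X, grid=gamma_grid(n=10), seed=4)
        assert np.array_equal(r1.errors, r2.errors)
        assert r1.gamma_opt == r2.gamma_opt

    def test_invalid_holdout_fraction(self):
        X = planted_share_matrix()
        with pytest.raises(ValueError):
            validate_path(X, holdout_fraction=0.9)

    def test_gamma_opt_interior_on_planted_matrix(self):
        """Hold-out error is minimised strictly inside the grid for >= 90%
        of 20 hold-out seeds on the planted sharing matrix."""
        X = planted_share_matrix()
        interior = 0
        for seed in range(20):
            res = validate_path(X, seed=seed)
            interior += 0 < res.index_opt < len(res.gammas) - 1
        assert interior >= 18

    def test_recovers_planted_clusters(self):
        X = planted_share_matrix()
        res = validate_path(X, seed=0)
        lab = res.col_clusters
        # columns b, b+3, b+6, b+9 belong to planted cluster b
        truth = np.arange(12) % 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, lab) == 1.0
        assert adjusted_rand_score(truth, res.row_clusters) == 1.0


class TestExtraction:
    def test_two_groups(self):
        U = np.array([[1.0, 1.0, 5.0], [1.0, 1.0, 5.0]])
        _, col = extract_clusters(U, tol_cluster=0.01)
        assert col[0] == col[1] != col[2]

    def test_huge_tolerance_single_cluster(self):
        U = np.array([[1.0, 1.0, 5.0], [1.0, 1.0, 5.0]])
        _, col = extract_clusters(U, tol_cluster=100.0)
        assert len(set(col)) == 1

    def test_coarsening_on_separated_blocks(self):
        """Cluster count never increases with gamma on a well-separated
        two-block instance with complete fusion graphs."""
        rng = np.random.default_rng(0)
        X = np.array(
            [[5.0, 5, 0, 0], [5, 5, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]]
        ) + rng.normal(0, 0.05, (4, 4))
        W = build_weights(X, k=3, phi=0.5)
        counts = []
        U = None
        for gamma in gamma_grid(n=25):
            U, _ = cobra_solve(X, W, gamma, U0=U)
            counts.append(len(set(extract_clusters(U)[1])))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_coarsening_up_to_validation_optimum(self):
        """On the planted sharing matrix the count is non-increasing over
        the segment of the path up to the selected gamma*."""
        X = planted_share_matrix()
        res = validate_path(X, seed=0)
        W = build_weights(X)
        counts = []
        U = None
        for gamma in res.gammas[: res.index_opt + 1]:
            U, _ = cobra_solve(X, W, gamma, U0=U)
            counts.append(len(set(extract_clusters(U)[1])))
        assert all(b <= a for a, b in zip(counts, counts[1:]))
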