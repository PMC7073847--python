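"""Gram matrices, sparse node-wise solvers, and bias-corrected statistics."""

import numpy as np
import pytest
from scipy.optimize import minimize

from npndiff import (
    ObservedMatrix,
    band_precision,
    bias_corrected_stat,
    gram_matrix,
    impute_latent,
    nodewise_dantzig,
    nodewise_lasso,
    residual_stats,
    sample_nonparanormal,
    select_lambda_aic,
    threshold_partial_corr,
)
from npndiff.regression import fit_nodewise, lambda_grid


def random_pd_gram(p, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(p, p + 4))
    G = A @ A.T / (p + 4)
    d = np.sqrt(np.diag(G))
    return G / np.outer(d, d)


def lasso_objective(G, g, beta, lam):
    return 0.5 * beta @ G @ beta - g @ beta + lam * np.sum(np.abs(beta))


def reference_lasso(G, g, lam):
    """Independent solve of the Gram-lasso via L-BFGS-B on the u/v split."""
    q = g.size

    def f(x):
        beta = x[:q] - x[q:]
        return lasso_objective(G, g, beta, 0.0) + lam * np.sum(x)

    def grad(x):
        beta = x[:q] - x[q:]
        core = G @ beta - g
        return np.concatenate([core + lam, -core + lam])

    res = minimize(
        f, np.zeros(2 * q), jac=grad, method="L-BFGS-B",
        bounds=[(0, None)] * 2 * q,
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 20_000},
    )
    return res.x[:q] - res.x[q:]


class TestGramMatrix:
    def test_adjusted_spearman_self_correlation_is_one(self, gaussian_matrix):
        G = gram_matrix(gaussian_matrix, source="adjusted_spearman")
        assert np.allclose(np.diag(G), 1.0)
        # identity 2*sin(pi/6) = 1 underlies the diagonal
        assert 2 * np.sin(np.pi / 6) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transforms(self, gaussian_matrix):
        G1 = gram_matrix(gaussian_matrix, source="adjusted_spearman")
        Y = gaussian_matrix.values.copy()
        Y[:, 0] = np.exp(Y[:, 0])
        Y[:, 1] = Y[:, 1] ** 3
        G2 = gram_matrix(ObservedMatrix(values=Y), source="adjusted_spearman")
        assert np.allclose(G1, G2, atol=1e-12)

    def test_consistent_for_latent_correlation(self):
        rng = np.random.default_rng(5)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        Y = rng.multivariate_normal(np.zeros(2), cov, size=5000)
        Y[:, 1] = np.exp(Y[:, 1])  # monotone marginal distortion
        G = gram_matrix(ObservedMatrix(values=Y), source="adjusted_spearman")
        assert abs(G[0, 1] - 0.5) < 0.05

    def test_rejects_constant_column(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError):
            gram_matrix(type("D", (), {"values": X})(), source="imputed")


class TestNodewiseLasso:
    def test_large_lambda_kills_all_coefficients(self):
        G = random_pd_gram(5, 0)
        lam = np.max(np.abs(np.delete(G[:, 2], 2)))
        assert np.allclose(nodewise_lasso(G, 2, lam), 0.0)

    def test_zero_lambda_equals_linear_solve(self):
        G = random_pd_gram(3, 1)
        keep = np.array([0, 2])
        expected = np.linalg.solve(G[np.ix_(keep, keep)], G[keep, 1])
        assert np.allclose(nodewise_lasso(G, 1, 0.0), expected, atol=1e-6)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_objective_matches_independent_solver(self, seed):
        G_full = random_pd_gram(4, seed)
        j = 0
        keep = np.arange(4) != j
        G, g = G_full[np.ix_(keep, keep)], G_full[keep, j]
        mine = nodewise_lasso(G_full, j, 0.1)
        ref = reference_lasso(G, g, 0.1)
        assert lasso_objective(G, g, mine, 0.1) == pytest.approx(
            lasso_objective(G, g, ref, 0.1), abs=1e-6
        )

    def test_rejects_asymmetric_gram(self):
        G = random_pd_gram(3, 5)
        G[0, 1] += 0.2
        with pytest.raises(ValueError):
            nodewise_lasso(G, 0, 0.1)


class TestNodewiseDantzig:
    def test_large_lambda_gives_zero(self):
        G = random_pd_gram(5, 6)
        lam = np.max(np.abs(np.delete(G[:, 1], 1))) + 0.01
        assert np.allclose(nodewise_dantzig(G, 1, lam), 0.0, atol=1e-9)

    def test_zero_lambda_equals_linear_solve(self):
        G = random_pd_gram(4, 7)
        keep = np.arange(4) != 2
        expected = np.linalg.solve(G[np.ix_(keep, keep)], G[keep, 2])
        assert np.allclose(nodewise_dantzig(G, 2, 0.0), expected, atol=1e-7)

    def test_constraint_holds_and_l1_no_larger_than_ols(self):
        G_full = random_pd_gram(4, 8)
        j, lam = 0, 0.05
        keep = np.arange(4) != j
        G, g = G_full[np.ix_(keep, keep)], G_full[keep, j]
        beta = nodewise_dantzig(G_full, j, lam)
        assert np.max(np.abs(G @ beta - g)) <= lam + 1e-8
        ols = np.linalg.solve(G, g)
        assert np.sum(np.abs(beta)) <= np.sum(np.abs(ols)) + 1e-8


class TestLambdaSelection:
    def test_grid_is_decreasing_with_requested_length(self):
        G = random_pd_gram(6, 9)
        grid = lambda_grid(G, 0, n_lambdas=20)
        assert grid.size == 20
        assert np.all(np.diff(grid) < 0)
        assert grid[0] == pytest.approx(np.max(np.abs(np.delete(G[:, 0], 0))))

    def test_path_top_is_intercept_only(self, gaussian_matrix):
        # at lambda_max the fit has empty support, so its AIC is the
        # intercept-only n*log(RSS0/n)
        imp = impute_latent(gaussian_matrix)
        G = gram_matrix(imp, source="imputed")
        grid = lambda_grid(G, 0, n_lambdas=5)
        top = nodewise_lasso(G, 0, grid[0])
        assert np.allclose(top, 0.0)

    def test_null_graph_selects_sparse_model(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(400, 8))
        imp = impute_latent(ObservedMatrix(values=Y))
        n_spurious = []
        for j in range(8):
            _, beta = select_lambda_aic(imp, j, method="lasso")
            n_spurious.append(np.count_nonzero(beta))
        assert np.mean(n_spurious) <= 2

    def test_dantzig_route_runs(self, gaussian_matrix):
        imp = impute_latent(gaussian_matrix)
        lam, beta = select_lambda_aic(imp, 0, method="dantzig", n_lambdas=5)
        assert lam > 0 and beta.size == imp.p - 1


class TestResidualStats:
    def test_zero_coefficients_reduce_to_centered_columns(self, gaussian_matrix):
        imp = impute_latent(gaussian_matrix)
        fit = residual_stats(imp, np.zeros((imp.p, imp.p)))
        centered = imp.values - imp.values.mean(axis=0)
        assert np.allclose(fit.residuals, centered)
        assert np.allclose(fit.cross_products, centered.T @ centered / imp.n)

    def test_residual_means_vanish(self, small_band_pair):
        _, (obs1, _), _ = small_band_pair
        imp = impute_latent(obs1)
        fit = fit_nodewise(imp, observed=obs1)
        scale = np.abs(fit.residuals).max()
        assert np.max(np.abs(fit.residuals.mean(axis=0))) < 1e-8 * scale

    def test_hand_computed_cross_products(self):
        Y = np.array([[1.0, 2, 0], [2, 4, 1], [3, 6, 0], [6, 0, 3]])
        imp = impute_latent(ObservedMatrix(values=Y))
        imp.values = Y  # use the raw integers for the hand computation
        fit = residual_stats(imp, np.zeros((3, 3)))
        centered = Y - Y.mean(axis=0)
        expected = centered.T @ centered / 4
        assert np.allclose(fit.cross_products, expected)
        # spot-check one entry against pencil arithmetic:
        # col0 centered (-2,-1,0,3), col2 centered (-1,0,-1,2) -> dot 8, /4 = 2
        assert fit.cross_products[0, 2] == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self, gaussian_matrix):
        imp = impute_latent(gaussian_matrix)
        with pytest.raises(ValueError):
            residual_stats(imp, np.zeros((2, 2)))


class TestBiasCorrectedStat:
    def test_zero_fit_reduces_to_residual_correlation(self, gaussian_matrix):
        imp = impute_latent(gaussian_matrix)
        fit = residual_stats(imp, np.zeros((imp.p, imp.p)))
        stats = bias_corrected_stat(fit)
        r = fit.cross_products
        expected = r / np.sqrt(np.outer(np.diag(r), np.diag(r)))
        off = ~np.eye(imp.p, dtype=bool)
        assert np.allclose(stats.rho_corrected[off], expected[off])
        assert np.all(np.abs(stats.rho_corrected[off]) <= 1)

    def test_statistic_matrices_symmetric(self, small_band_pair):
        _, (obs1, _), _ = small_band_pair
        fit = fit_nodewise(impute_latent(obs1), observed=obs1)
        stats = bias_corrected_stat(fit)
        assert np.allclose(stats.s_star, stats.s_star.T, atol=1e-12)
        assert np.allclose(stats.rho_corrected, stats.rho_corrected.T, atol=1e-12)

    def test_recovers_true_partial_correlations(self):
        # known 3x3 precision matrix with unequal diagonals
        omega = np.array([[2.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.5]])
        rng = np.random.default_rng(12)
        Y = rng.multivariate_normal(np.zeros(3), np.linalg.inv(omega), size=5000)
        obs = ObservedMatrix(values=Y)
        fit = fit_nodewise(impute_latent(obs), observed=obs)
        stats = bias_corrected_stat(fit)
        d = np.sqrt(np.diag(omega))
        for i in range(3):
            for j in range(i + 1, 3):
                true_rho = -omega[i, j] / (d[i] * d[j])
                assert abs(stats.rho_corrected[i, j] - true_rho) < 0.05


class TestThreshold:
    def test_small_entries_zeroed_large_kept(self):
        from npndiff.regression import ClassGraphStats

        p, n = 200, 100
        rho = np.zeros((p, p))
        rho[0, 1] = rho[1, 0] = 0.9
        rho[2, 3] = rho[3, 2] = 0.01
        np.fill_diagonal(rho, 1.0)
        stats = ClassGraphStats(
            s_star=rho, rho_corrected=rho, rho_thresholded=np.zeros_like(rho), n=n, p=p
        )
        out = threshold_partial_corr(stats)
        cutoff = 2 * np.sqrt(np.log(p) / n)
        assert 0.9 >= cutoff and 0.01 < cutoff  # cutoff ~ 0.4605
        assert out[0, 1] == 0.9
        assert out[2, 3] == 0.0

    def test_idempotent(self, small_band_pair):
        _, (obs1, _), _ = small_band_pair
        stats = bias_corrected_stat(fit_nodewise(impute_latent(obs1), observed=obs1))
        once = threshold_partial_corr(stats)
        stats.rho_corrected = once
        twice = threshold_partial_corr(stats)
        assert np.array_equal(once, twice)


def test_gram_lasso_matches_sklearn_on_data_gram():
    # the Gram objective with G = X'X/n equals sklearn's lasso objective
    sklearn = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(13)
    X = rng.normal(size=(200, 5))
    X = (X - X.mean(0)) / X.std(0)
    G = X.T @ X / 200
    lam = 0.1
    mine = nodewise_lasso(G, 0, lam)
    model = sklearn.Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=100_000)
    model.fit(X[:, 1:], X[:, 0])
    assert np.allclose(mine, model.coef_, atol=1e-6)
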