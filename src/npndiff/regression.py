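"""Per-class node-wise regression and bias-corrected partial correlations.

For a Gaussian vector X with precision matrix Omega, regressing each node on
the others,

    X_j = alpha_j + X_{-j}' beta_j + eps_j,

gives beta_j = -Omega_{-j,j} / omega_jj and cov(eps_i, eps_j) =
omega_ij / (omega_ii omega_jj).  Residual cross-products of regularized fits
are biased by the shrinkage of beta-hat; augmenting them with the
coefficient-weighted residual variances removes the first-order bias:

    N_ij = r_ij + r_ii * B[j,i] + r_jj * B[i,j],

where B[a,b] is the fitted coefficient of variable b in the regression of
variable a and r_ij = (1/n) sum_m eps_mi eps_mj.  The partial-correlation
scale estimate rho_ij = N_ij / sqrt(r_ii r_jj) is consistent for
rho_ij. = -omega_ij / sqrt(omega_ii omega_jj).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from ._solvers import gram_dantzig, gram_lasso, gram_lasso_path
from .npn import ImputedMatrix

__all__ = [
    "NodewiseFit",
    "ClassGraphStats",
    "gram_matrix",
    "nodewise_lasso",
    "nodewise_dantzig",
    "lambda_grid",
    "select_lambda_aic",
    "fit_nodewise",
    "residual_stats",
    "bias_corrected_stat",
    "threshold_partial_corr",
]

RHO_CLIP = 1.0 - 1e-10


@dataclass
class NodewiseFit:
    """Node-wise regression results for one class.

    ``coefficients[j, i]`` holds the coefficient of variable i in the
    regression of variable j (zero diagonal).  Residuals are computed on the
    imputed data regardless of which Gram matrix produced the coefficients.
    """

    coefficients: np.ndarray
    intercepts: np.ndarray
    residuals: np.ndarray
    cross_products: np.ndarray
    lambda_used: np.ndarray
    method: str
    gram_source: str

    @property
    def n(self) -> int:
        return self.residuals.shape[0]

    @property
    def p(self) -> int:
        return self.residuals.shape[1]


@dataclass
class ClassGraphStats:
    """Bias-corrected edge statistics for one class.

    ``s_star`` is the raw bias-corrected statistic with the r_ii * r_jj
    denominator (inverse-covariance scale); ``rho_corrected`` is the bounded
    partial-correlation-scale estimate used by the downstream test, and
    ``rho_thresholded`` zeroes entries below the 2*sqrt(log(p)/n) cutoff.
    """

    s_star: np.ndarray
    rho_corrected: np.ndarray
    rho_thresholded: np.ndarray
    n: int
    p: int


def gram_matrix(data, source: str = "adjusted_spearman") -> np.ndarray:
    """Correlation-scale Gram matrix of a data matrix.

    source="imputed" uses the Pearson correlation of the (imputed) columns;
    source="adjusted_spearman" applies 2*sin(pi*rho_S/6) entrywise to the
    Spearman rank correlation, which is a consistent estimator of the latent
    Gaussian correlation under any strictly increasing marginal transforms.
    """
    X = data.values if hasattr(data, "values") else np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("gram matrix requires n >= 4")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column in data")
    if source == "imputed":
        G = np.corrcoef(X, rowvar=False)
    elif source == "adjusted_spearman":
        rho_s = spearmanr(X).statistic
        if np.ndim(rho_s) == 0:  # scipy collapses the p=2 case to a scalar
            rho_s = np.array([[1.0, rho_s], [rho_s, 1.0]])
        G = 2.0 * np.sin(np.pi * rho_s / 6.0)
    else:
        raise ValueError(f"unknown gram source {source!r}")
    np.fill_diagonal(G, 1.0)
    return (G + G.T) / 2.0


def nodewise_lasso(gram: np.ndarray, j: int, lam: float, **kw) -> np.ndarray:
    """Lasso coefficients of node j given a Gram matrix (length p-1)."""
    return gram_lasso(gram, j, lam, **kw)


def nodewise_dantzig(gram: np.ndarray, j: int, lam: float) -> np.ndarray:
    """Dantzig-selector coefficients of node j given a Gram matrix."""
    return gram_dantzig(gram, j, lam)


def lambda_grid(
    gram: np.ndarray,
    j: int,
    n_lambdas: int = 20,
    min_ratio: float = 0.25,
    n: int | None = None,
) -> np.ndarray:
    """Decreasing log-spaced penalty grid for the node-j solution path.

    Runs from lambda_max = max_i |G_ij| down to lambda_max * min_ratio, but
    never below the universal noise level sqrt(2 log(p) / n) when the sample
    size is supplied: below that level the path admits predictors whose
    sample correlation with the target is indistinguishable from noise, and
    the post-selection AIC comparison is optimistic for exactly those
    candidates.
    """
    if n_lambdas < 2:
        raise ValueError("need at least 2 grid points")
    if not 0.0 < min_ratio < 1.0:
        raise ValueError("min_ratio must lie in (0, 1)")
    p = gram.shape[0]
    keep = np.arange(p) != j
    lam_max = float(np.max(np.abs(gram[keep, j])))
    if lam_max <= 0:
        lam_max = 1e-3
    lam_min = lam_max * min_ratio
    if n is not None:
        noise_floor = float(np.sqrt(2.0 * np.log(p) / n))
        lam_min = min(max(lam_min, noise_floor), 0.999 * lam_max)
    return np.geomspace(lam_max, lam_min, n_lambdas)


def _refit_ols(X: np.ndarray, j: int, beta: np.ndarray) -> np.ndarray:
    """OLS refit of node j restricted to the support of ``beta``."""
    n, p = X.shape
    keep = np.arange(p) != j
    supp = np.flatnonzero(beta)
    out = np.zeros_like(beta)
    if supp.size == 0 or supp.size >= n - 2:
        return out if supp.size == 0 else beta
    A = np.column_stack([np.ones(n), X[:, keep][:, supp]])
    coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
    out[supp] = coef[1:]
    return out


def select_lambda_aic(
    imputed: ImputedMatrix,
    j: int,
    method: str = "lasso",
    n_lambdas: int = 20,
    gram: np.ndarray | None = None,
    refit: bool = True,
    min_ratio: float = 0.25,
) -> tuple[float, np.ndarray]:
    """Pick lambda for node j by AIC along a solution path (default 20 points).

    AIC = n * log(RSS/n) + 2 * df, with RSS evaluated on the imputed data and
    df the support size of the fit.  Ties resolve to the larger lambda.  With
    ``refit=True`` (default) each candidate's coefficients are re-estimated
    by ordinary least squares on its selected support before scoring — the
    relaxed-lasso / Gauss-Dantzig hybrid, which removes the shrinkage bias
    that the downstream first-order correction cannot fully absorb in finite
    samples.
    """
    X = imputed.values
    n, p = X.shape
    if gram is None:
        gram = gram_matrix(imputed, source="imputed")
    grid = lambda_grid(gram, j, n_lambdas, min_ratio, n=n)
    keep = np.arange(p) != j
    if method == "lasso":
        path = gram_lasso_path(gram, j, grid)
    elif method == "dantzig":
        path = np.stack([gram_dantzig(gram, j, lam) for lam in grid])
    else:
        raise ValueError(f"unknown method {method!r}")
    if refit:
        path = np.stack([_refit_ols(X, j, beta) for beta in path])

    Xj = X[:, j]
    Xmj = X[:, keep]
    best_idx, best_aic = 0, np.inf
    for idx, beta in enumerate(path):
        fitted = Xmj @ beta
        alpha = Xj.mean() - fitted.mean()
        rss = float(np.sum((Xj - alpha - fitted) ** 2))
        df = int(np.count_nonzero(beta))
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * df
        if aic < best_aic:  # strict: ties keep the earlier (larger) lambda
            best_aic, best_idx = aic, idx
    return float(grid[best_idx]), path[best_idx]


def fit_nodewise(
    imputed: ImputedMatrix,
    method: str = "lasso",
    gram_source: str = "adjusted_spearman",
    n_lambdas: int = 20,
    observed=None,
    refit: bool = True,
    min_ratio: float = 0.25,
) -> NodewiseFit:
    """AIC-tuned node-wise fit of every node, residuals on the imputed data.

    With gram_source="adjusted_spearman" the Gram matrix is computed from the
    rank correlations of the observed data when available (rank statistics
    are identical on observed and imputed columns), matching the rank-based
    lasso / Dantzig selector estimators.
    """
    gram_data = observed if (observed is not None and gram_source == "adjusted_spearman") else imputed
    gram = gram_matrix(gram_data, source=gram_source)
    p = imputed.p
    B = np.zeros((p, p))
    lambdas = np.zeros(p)
    for j in range(p):
        lam, beta = select_lambda_aic(
            imputed, j, method=method, n_lambdas=n_lambdas, gram=gram,
            refit=refit, min_ratio=min_ratio,
        )
        lambdas[j] = lam
        B[j, np.arange(p) != j] = beta
    fit = residual_stats(imputed, B)
    fit.lambda_used = lambdas
    fit.method = method
    fit.gram_source = gram_source
    return fit


def residual_stats(imputed: ImputedMatrix, coefficients: np.ndarray) -> NodewiseFit:
    """Intercepts, residuals and residual cross-products for given B-hat."""
    X = imputed.values
    n, p = X.shape
    B = np.asarray(coefficients, dtype=float)
    if B.shape != (p, p):
        raise ValueError(f"coefficient matrix must be {p}x{p}, got {B.shape}")
    if np.any(np.diag(B) != 0):
        raise ValueError("coefficient matrix must have zero diagonal")
    means = X.mean(axis=0)
    # alpha_j = mean(X_j) - mean(X_{-j})' beta_j ; diagonal of B is zero so
    # the full-matrix product is the restricted one.
    intercepts = means - B @ means
    residuals = X - intercepts - X @ B.T
    cross = residuals.T @ residuals / n
    return NodewiseFit(
        coefficients=B,
        intercepts=intercepts,
        residuals=residuals,
        cross_products=cross,
        lambda_used=np.zeros(p),
        method="",
        gram_source="",
    )


def bias_corrected_stat(fit: NodewiseFit) -> ClassGraphStats:
    """Bias-corrected edge statistics from a node-wise fit.

    N_ij = r_ij + r_ii B[j,i] + r_jj B[i,j] cancels the first-order shrinkage
    bias of the residual cross-product; its population limit is
    -omega_ij / (omega_ii omega_jj).
    """
    r = fit.cross_products
    d = np.diag(r)
    if np.any(d <= 0):
        raise RuntimeError("zero residual variance; cannot form statistics")
    B = fit.coefficients
    N = r + d[:, None] * B.T + d[None, :] * B
    denom = np.sqrt(np.outer(d, d))
    s_star = N / np.outer(d, d)
    rho = np.clip(N / denom, -RHO_CLIP, RHO_CLIP)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(s_star, 1.0 / d)
    stats = ClassGraphStats(
        s_star=s_star,
        rho_corrected=rho,
        rho_thresholded=np.zeros_like(rho),
        n=fit.n,
        p=fit.p,
    )
    stats.rho_thresholded = threshold_partial_corr(stats)
    return stats


def threshold_partial_corr(stats: ClassGraphStats) -> np.ndarray:
    """Hard-threshold the partial correlations at 2*sqrt(log(p)/n).

    Entries below the cutoff in magnitude are set to zero; this estimator
    feeds the variance term of the two-sample statistic.  Idempotent.
    """
    if stats.p < 2 or stats.n < 2:
        raise ValueError("thresholding requires p >= 2 and n >= 2")
    cutoff = 2.0 * np.sqrt(np.log(stats.p) / stats.n)
    out = np.where(np.abs(stats.rho_corrected) >= cutoff, stats.rho_corrected, 0.0)
    np.fill_diagonal(out, 1.0)
    return out
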