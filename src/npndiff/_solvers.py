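"""Low-level sparse-regression solvers operating on a Gram matrix.

Both solvers work purely from second moments: for target node j with Gram
matrix G (correlation scale), the lasso problem is

    min_beta  (1/2) beta' G_{-j,-j} beta - G_{-j,j}' beta + lam ||beta||_1

solved by cyclic coordinate descent with soft-thresholding, and the Dantzig
selector is

    min ||beta||_1  s.t.  || G_{-j,-j} beta - G_{-j,j} ||_inf <= lam

solved as a linear program after the usual positive/negative split.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from scipy.optimize import linprog

__all__ = ["gram_lasso", "gram_dantzig", "gram_lasso_path"]

_TOL = 1e-7
_MAX_SWEEPS = 10_000


@njit(cache=False)
def _cd_gram_lasso(G, g, lam, beta, tol, max_sweeps):  # pragma: no cover - jitted
    q = g.shape[0]
    for _ in range(max_sweeps):
        max_change = 0.0
        for i in range(q):
            old = beta[i]
            # partial residual correlation for coordinate i
            z = g[i] - np.dot(G[i], beta) + G[i, i] * old
            if z > lam:
                new = (z - lam) / G[i, i]
            elif z < -lam:
                new = (z + lam) / G[i, i]
            else:
                new = 0.0
            if new != old:
                beta[i] = new
                change = abs(new - old)
                if change > max_change:
                    max_change = change
        if max_change < tol:
            return True
    return False


def _check_gram(gram: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    gram = np.asarray(gram, dtype=float)
    p = gram.shape[0]
    if gram.shape != (p, p) or not np.allclose(gram, gram.T, atol=1e-10):
        raise ValueError("gram matrix must be square and symmetric")
    if not 0 <= j < p:
        raise ValueError(f"target index {j} out of range for p={p}")
    if np.any(np.diag(gram) <= 0):
        raise ValueError("gram matrix must have positive diagonal")
    keep = np.arange(p) != j
    return gram[np.ix_(keep, keep)], gram[keep, j]


def gram_lasso(
    gram: np.ndarray,
    j: int,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = _TOL,
    max_sweeps: int = _MAX_SWEEPS,
) -> np.ndarray:
    """Lasso coefficients for node j from a Gram matrix; length p-1."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    G, g = _check_gram(gram, j)
    beta = np.zeros(g.size) if beta0 is None else np.array(beta0, dtype=float)
    converged = _cd_gram_lasso(G, g, float(lam), beta, tol, max_sweeps)
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge for node {j} at lambda={lam:g}; "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return beta


def gram_lasso_path(
    gram: np.ndarray,
    j: int,
    lambdas: np.ndarray,
    tol: float = _TOL,
    max_sweeps: int = _MAX_SWEEPS,
) -> np.ndarray:
    """Warm-started lasso solutions along a decreasing lambda grid.

    Returns an array of shape (len(lambdas), p-1).
    """
    G, g = _check_gram(gram, j)
    out = np.zeros((len(lambdas), g.size))
    beta = np.zeros(g.size)
    for idx, lam in enumerate(lambdas):
        _cd_gram_lasso(G, g, float(lam), beta, tol, max_sweeps)
        out[idx] = beta
    return out


def gram_dantzig(gram: np.ndarray, j: int, lam: float) -> np.ndarray:
    """Dantzig-selector coefficients for node j; length p-1.

    Split beta = u - v with u, v >= 0; minimize 1'(u+v) subject to
    -lam <= G(u - v) - g <= lam.  beta = G^{-1} g is always feasible for
    lam >= 0 when G is invertible, but the solver result is still verified.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    G, g = _check_gram(gram, j)
    q = g.size
    c = np.ones(2 * q)
    block = np.hstack([G, -G])
    A_ub = np.vstack([block, -block])
    b_ub = np.concatenate([g + lam, lam - g])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"Dantzig LP failed for node {j}: {res.message}")
    beta = res.x[:q] - res.x[q:]
    return beta
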