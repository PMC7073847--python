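"""Winsorized estimation of the latent Gaussian layer of a nonparanormal model.

A random vector Y follows a nonparanormal distribution when some set of
strictly increasing marginal transformations f = (f_1, ..., f_p) maps it to a
multivariate Gaussian X = f(Y).  The transformations are unknown in practice,
but because each f_j is monotone it can be estimated through the marginal
empirical CDF: the normal-scores map

    x*_mj = mu_j + sigma_j * Phi^{-1}( F~_j(y_mj) )

imputes the latent Gaussian data up to location and scale.  The raw empirical
CDF reaches 1 at the sample maximum, where Phi^{-1} diverges, so F~ is the
Winsorized (truncated) eCDF, clamped to [delta_n, 1 - delta_n] with the
truncation level

    delta_n = 1 / (4 n^{1/4} sqrt(pi log n)),

which balances the bias introduced by clamping against the tail variance of
the eCDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ObservedMatrix",
    "WinsorizedTransform",
    "ImputedMatrix",
    "truncation_parameter",
    "winsorized_cdf",
    "impute_latent",
    "imputed_covariance",
]


@dataclass
class ObservedMatrix:
    """A per-class observed data matrix (samples in rows, variables in columns).

    Marginals may be arbitrarily non-Gaussian; only the ranks within each
    column carry dependence information under the nonparanormal model.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variable_ids: list[str] = field(default_factory=list)
    class_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x variables)")
        n, p = self.values.shape
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 variables, got {p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observed matrix contains non-finite entries")
        if not self.sample_ids:
            self.sample_ids = [f"s{m}" for m in range(n)]
        if not self.variable_ids:
            self.variable_ids = [f"v{j}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.variable_ids) != p:
            raise ValueError("id lengths do not match matrix shape")
        for j in range(p):
            if np.unique(self.values[:, j]).size < 2:
                raise ValueError(
                    f"column {self.variable_ids[j]} is constant; "
                    "every variable needs at least two distinct values"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class WinsorizedTransform:
    """Per-variable Winsorized eCDF together with raw location/scale estimates.

    ``sigma_hat`` uses the 1/n normalization.  ``ecdf_values`` maps, for each
    variable, observed value -> truncated probability; ties share a value.
    """

    delta_n: float
    mu_hat: np.ndarray
    sigma_hat: np.ndarray
    ecdf_values: list[dict[float, float]]


@dataclass
class ImputedMatrix:
    """Imputed latent Gaussian data X* with its 1/n-normalized covariance."""

    values: np.ndarray
    transform: WinsorizedTransform
    covariance: np.ndarray
    variable_ids: list[str] = field(default_factory=list)
    class_label: str = ""

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def truncation_parameter(n: int) -> float:
    """Winsorization level delta_n = 1 / (4 n^{1/4} sqrt(pi log n)).

    Natural logarithm; strictly decreasing in n, tending to 0, so the clamp
    vanishes asymptotically and the estimator is consistent.
    """
    if n < 2:
        raise ValueError("truncation parameter requires n >= 2")
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


def winsorized_cdf(column: np.ndarray, delta_n: float) -> np.ndarray:
    """Truncated eCDF of ``column`` evaluated at its own entries.

    F_hat(t) = (1/n) #{values <= t}, clamped to [delta_n, 1 - delta_n].
    Tied values receive identical probabilities.
    """
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValueError("empty column")
    if not 0.0 < delta_n < 0.5:
        raise ValueError(f"delta_n must lie in (0, 1/2), got {delta_n}")
    n = column.size
    # #{values <= t} via searchsorted on the sorted column (right side).
    order = np.sort(column)
    raw = np.searchsorted(order, column, side="right") / n
    return np.clip(raw, delta_n, 1.0 - delta_n)


def impute_latent(
    data: ObservedMatrix,
    delta_override: float | None = None,
    standardize: str = "raw",
) -> ImputedMatrix:
    """Impute the latent Gaussian matrix X* from observed data.

    Per column j: X*_mj = mu_j + sigma_j * Phi^{-1}(F~_j(Y_mj)), where mu_j
    and sigma_j are the raw column mean and 1/n-scale (``standardize="raw"``,
    the default) or 0 and 1 (``standardize="latent"``).  Also computes the
    1/n-normalized covariance of the imputed columns.
    """
    if standardize not in ("raw", "latent"):
        raise ValueError("standardize must be 'raw' or 'latent'")
    Y = data.values
    n, p = Y.shape
    delta_n = truncation_parameter(n) if delta_override is None else float(delta_override)
    if not 0.0 < delta_n < 0.5:
        raise ValueError(f"delta_n must lie in (0, 1/2), got {delta_n}")

    if standardize == "raw":
        mu = Y.mean(axis=0)
        sigma = np.sqrt(np.mean((Y - mu) ** 2, axis=0))  # 1/n normalization
    else:
        mu = np.zeros(p)
        sigma = np.ones(p)
    if np.any(sigma == 0):
        j = int(np.argmin(sigma))
        raise ValueError(f"column {data.variable_ids[j]} has zero scale")

    X = np.empty_like(Y)
    ecdf_maps: list[dict[float, float]] = []
    for j in range(p):
        probs = winsorized_cdf(Y[:, j], delta_n)
        X[:, j] = mu[j] + sigma[j] * norm.ppf(probs)
        ecdf_maps.append(dict(zip(Y[:, j].tolist(), probs.tolist())))

    transform = WinsorizedTransform(
        delta_n=delta_n, mu_hat=mu, sigma_hat=sigma, ecdf_values=ecdf_maps
    )
    cov = _centered_cross_product(X)
    return ImputedMatrix(
        values=X,
        transform=transform,
        covariance=cov,
        variable_ids=list(data.variable_ids),
        class_label=data.class_label,
    )


def _centered_cross_product(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    centered = X - X.mean(axis=0)
    return centered.T @ centered / n


def imputed_covariance(imputed: ImputedMatrix) -> np.ndarray:
    """1/n-normalized centered cross-product matrix of the imputed data."""
    if imputed.n < 2:
        raise ValueError("covariance requires n >= 2")
    return _centered_cross_product(imputed.values)
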