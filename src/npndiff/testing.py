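"""Multi-class differential-edge test with empirically corrected FDR control.

For classes k < k' the standardized two-sample statistic per edge (i, j) is

    S_ij^(k,k') = (rho_ij^(k) - rho_ij^(k'))
                  / sqrt( (1 - rho~_k^2)^2 / n_k + (1 - rho~_k'^2)^2 / n_k' ),

with rho the bias-corrected partial-correlation estimates and rho~ their
hard-thresholded versions (variance plug-in).  The combined statistic
S_ij = sum_{k<k'} (S_ij^(k,k'))^2 is referred to a weighted chi-square law
with M = K(K-1)/2 terms and mapped to the normal scale,

    T_ij = Phi^{-1}( P( sum_m lam_m Z_m^2 <= S_ij ) ),

so that under the null T_ij is approximately standard normal.  The rejection
threshold t(alpha0) is the smallest t with

    1 - Phi(t) <= alpha0 * A(t) * max(1, #{T_ij >= t}) / (p(p-1)/2),

where A(t) = (1 + |A| |t| phi(t) / (2 (1 - Phi(t))))^{-1} and
A = (P0 - P0_hat) / Q0 corrects for empirical departure of the T's from
normality near the centre (P0 = 2 Phi(1) - 1, Q0 = 2 phi(1), P0_hat the
observed fraction with |T| <= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import chi2, norm, qmc

from .config import RunConfig
from .npn import ObservedMatrix, impute_latent
from .regression import ClassGraphStats, bias_corrected_stat, fit_nodewise

__all__ = [
    "DifferentialResult",
    "two_sample_stat",
    "multiclass_stat",
    "weighted_chisq_cdf",
    "t_transform",
    "fdr_threshold",
    "class_stats",
    "t_statistics",
    "call_differential_edges",
]

_CDF_CLAMP = 1e-15


@dataclass
class DifferentialResult:
    """Full output of the differential-edge test."""

    pairwise_stats: dict[tuple[int, int], np.ndarray]
    combined: np.ndarray
    t_stats: np.ndarray
    alpha0: float
    threshold: float
    rejected: set[tuple[int, int]]
    constants: dict[str, float]
    class_stats: list[ClassGraphStats] = field(default_factory=list)
    variable_ids: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.combined.shape[0]


def two_sample_stat(stats_k: ClassGraphStats, stats_k2: ClassGraphStats) -> np.ndarray:
    """Standardized difference of partial-correlation estimates per edge."""
    if stats_k.p != stats_k2.p:
        raise ValueError("classes have different numbers of variables")
    num = stats_k.rho_corrected - stats_k2.rho_corrected
    var = (1.0 - stats_k.rho_thresholded**2) ** 2 / stats_k.n
    var = var + (1.0 - stats_k2.rho_thresholded**2) ** 2 / stats_k2.n
    out = np.zeros_like(num)
    off = ~np.eye(num.shape[0], dtype=bool)
    out[off] = num[off] / np.sqrt(var[off])
    return out


def multiclass_stat(pairwise: dict[tuple[int, int], np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Entrywise sum of squares of the pairwise statistics."""
    mats = list(pairwise.values()) if isinstance(pairwise, dict) else list(pairwise)
    if not mats:
        raise ValueError("need at least one pairwise statistic")
    return np.sum([m**2 for m in mats], axis=0)


def weighted_chisq_cdf(s, weights) -> np.ndarray | float:
    """P( sum_m lam_m Z_m^2 <= s ) for iid standard normal Z_m.

    Closed forms for a single term and for equal weights (scaled chi-square);
    for unequal weights the law is evaluated by deterministic scrambled-Sobol
    quasi-Monte Carlo with 2^21 points (absolute error well below 1e-3).
    """
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if np.any(weights <= 0):
        raise ValueError("all weights must be positive")
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < 0):
        raise ValueError("s must be nonnegative")
    M = weights.size
    if np.allclose(weights, weights[0]):
        out = chi2.cdf(s_arr / weights[0], df=M)
    else:
        draws = np.sort(_mixture_draws(M) @ weights)
        out = np.searchsorted(draws, s_arr, side="right") / draws.size
        out[s_arr == 0.0] = 0.0
    return out if np.ndim(s) else float(out[0])


@lru_cache(maxsize=8)
def _mixture_draws(M: int) -> np.ndarray:
    """Squared-normal QMC draws (2^21 x M), fixed scramble seed."""
    sobol = qmc.Sobol(d=M, scramble=True, seed=1234567)
    u = sobol.random_base2(m=21)
    return norm.ppf(u) ** 2


def t_transform(combined: np.ndarray, weights) -> np.ndarray:
    """Map combined statistics to the normal scale, T = Phi^{-1}(CDF(S)).

    The CDF value is clamped to [1e-15, 1 - 1e-15] before inversion so every
    T is finite.
    """
    p = combined.shape[0]
    off = ~np.eye(p, dtype=bool)
    cdf_vals = np.asarray(weighted_chisq_cdf(combined[off], weights))
    T = np.zeros_like(combined)
    T[off] = norm.ppf(np.clip(cdf_vals, _CDF_CLAMP, 1.0 - _CDF_CLAMP))
    return T


def _correction_factor(t: float, A: float) -> float:
    tail = 1.0 - norm.cdf(t)
    if tail <= 0:
        return 1.0
    return 1.0 / (1.0 + abs(A) * abs(t) * norm.pdf(t) / (2.0 * tail))


def fdr_threshold(
    t_stats: np.ndarray, alpha0: float
) -> tuple[float, set[tuple[int, int]], dict[str, float]]:
    """Empirically corrected FDR threshold over the upper-triangle T's.

    Scans the sorted distinct observed T values in [0, sqrt(4 log p~)]
    (p~ = p(p-1)/2 hypotheses) for the smallest qualifying t; if none
    qualifies, falls back to t = sqrt(4 log p~) so only extreme statistics
    are rejected.  Rejection is one-sided: T_ij >= t.
    """
    if not 0.0 < alpha0 < 1.0:
        raise ValueError(f"alpha0 must lie in (0,1), got {alpha0}")
    p = t_stats.shape[0]
    if p < 2:
        raise ValueError("need p >= 2")
    iu = np.triu_indices(p, k=1)
    tri = t_stats[iu]
    p_tilde = tri.size

    P0 = 2.0 * norm.cdf(1.0) - 1.0
    Q0 = 2.0 * norm.pdf(1.0)
    P0_hat = float(np.mean(np.abs(tri) <= 1.0))
    A = (P0 - P0_hat) / Q0

    t_max = np.sqrt(4.0 * np.log(p_tilde))
    candidates = np.unique(tri[(tri >= 0.0) & (tri <= t_max)])
    threshold = t_max
    for t in candidates:
        R = int(np.sum(tri >= t))
        if 1.0 - norm.cdf(t) <= alpha0 * _correction_factor(t, A) * max(1, R) / p_tilde:
            threshold = float(t)
            break

    rejected = {
        (int(i), int(j))
        for i, j, tv in zip(iu[0], iu[1], tri)
        if tv >= threshold
    }
    constants = {"P0": P0, "P0_hat": P0_hat, "Q0": Q0, "A": A}
    return threshold, rejected, constants


def class_stats(data: ObservedMatrix, config: RunConfig | None = None) -> ClassGraphStats:
    """Impute, fit node-wise regressions and form one class's statistics."""
    config = config or RunConfig()
    imputed = impute_latent(data, delta_override=config.delta_override)
    fit = fit_nodewise(
        imputed,
        method=config.method,
        gram_source=config.gram_source,
        n_lambdas=config.n_lambdas,
        observed=data,
        refit=config.refit,
        min_ratio=config.lambda_min_ratio,
    )
    return bias_corrected_stat(fit)


def t_statistics(
    classes: list[ObservedMatrix], config: RunConfig | None = None
) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray], list[ClassGraphStats]]:
    """T matrix and pairwise statistics for K >= 2 classes.

    Exposed separately from :func:`call_differential_edges` so callers can
    threshold the same T matrix at several FDR levels without refitting.
    """
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    p = classes[0].p
    if any(c.p != p for c in classes):
        raise ValueError("all classes must share the variable set")
    config = config or RunConfig()
    stats = [class_stats(c, config) for c in classes]
    pairwise = {
        (k, k2): two_sample_stat(stats[k], stats[k2])
        for k in range(len(stats))
        for k2 in range(k + 1, len(stats))
    }
    combined = multiclass_stat(pairwise)
    weights = config.weights if config.weights is not None else np.ones(len(pairwise))
    T = t_transform(combined, weights)
    return T, pairwise, stats


def call_differential_edges(
    classes: list[ObservedMatrix],
    alpha0: float = 0.05,
    config: RunConfig | None = None,
) -> DifferentialResult:
    """End-to-end differential-edge test: impute, fit, combine, threshold."""
    config = config or RunConfig()
    T, pairwise, stats = t_statistics(classes, config)
    combined = multiclass_stat(pairwise)
    threshold, rejected, constants = fdr_threshold(T, alpha0)
    return DifferentialResult(
        pairwise_stats=pairwise,
        combined=combined,
        t_stats=T,
        alpha0=alpha0,
        threshold=threshold,
        rejected=rejected,
        constants=constants,
        class_stats=stats,
        variable_ids=list(classes[0].variable_ids),
    )
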