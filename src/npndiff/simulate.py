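"""Synthetic benchmarks: paired precision matrices, nonparanormal sampling,
and empirical FDR / power scoring of the differential-edge test.

Two graph families are generated.  The band graph has omega_ii = 1,
omega_ij = 0.6 for |i-j| = 1 and 0 otherwise; a chosen number of the
first-off-diagonal edges flip sign in the second class, and
max(|lambda_min(Omega1)|, |lambda_min(Omega2)|) + 0.05 is added to both
diagonals to enforce positive definiteness.  The Erdos-Renyi graph connects
each pair with probability 5%, draws edge weights uniformly on
+/-[1/4, 1/2], shrinks off-diagonals by a factor of 5 with unit diagonal,
and flips the sign of 5% of the edges in the second class.

Observed data are latent Gaussian draws from N(0, Omega^{-1}) pushed through
strictly increasing marginal transforms (identity reproduces the oracle-data
arm); the latent draw is retained so both arms can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import logistic

from .config import RunConfig
from .npn import ObservedMatrix
from .testing import fdr_threshold, t_statistics

__all__ = [
    "PrecisionModel",
    "PerformanceReport",
    "TRANSFORMS",
    "band_precision",
    "er_precision",
    "sample_nonparanormal",
    "evaluate_performance",
]

# Strictly increasing marginal transforms for the nonparanormal arm.
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "exp": np.exp,
    "cube": lambda x: x**3,
    # maps the latent Gaussian through the standard logistic quantile scale
    "logistic_quantile": lambda x: logistic.ppf(
        np.clip(0.5 * (1.0 + np.tanh(x / 2.0)), 1e-12, 1.0 - 1e-12)
    ),
}


@dataclass
class PrecisionModel:
    """Ground truth for one two-class simulation scenario."""

    omega1: np.ndarray
    omega2: np.ndarray
    differential_edges: set[tuple[int, int]]
    graph_type: str
    transform_labels: list[str]
    seed: int

    @property
    def p(self) -> int:
        return self.omega1.shape[0]


@dataclass
class PerformanceReport:
    """Average empirical FDR and power over simulation replicates."""

    alpha_grid: list[float]
    efdr: list[float]
    power: list[float]
    reps: int
    meta: dict = field(default_factory=dict)


def _pd_adjust(omega1: np.ndarray, omega2: np.ndarray, margin: float = 0.05) -> float:
    """Shared diagonal shift making both matrices positive definite."""
    lmin1 = float(np.linalg.eigvalsh(omega1)[0])
    lmin2 = float(np.linalg.eigvalsh(omega2)[0])
    return max(abs(lmin1), abs(lmin2)) + margin


def band_precision(p: int, n_flips: int, seed: int = 0) -> PrecisionModel:
    """Tridiagonal {1, 0.6} precision pair with sign-flipped differential edges."""
    if p < 3:
        raise ValueError("band graph requires p >= 3")
    if not 0 <= n_flips <= p - 1:
        raise ValueError(f"n_flips must lie in [0, {p - 1}]")
    rng = np.random.default_rng(seed)
    omega1 = np.eye(p) + 0.6 * (np.eye(p, k=1) + np.eye(p, k=-1))
    omega2 = omega1.copy()
    flip_idx = rng.choice(p - 1, size=n_flips, replace=False)
    edges = set()
    for i in flip_idx:
        omega2[i, i + 1] *= -1.0
        omega2[i + 1, i] *= -1.0
        edges.add((int(i), int(i + 1)))
    shift = _pd_adjust(omega1, omega2)
    omega1 = omega1 + shift * np.eye(p)
    omega2 = omega2 + shift * np.eye(p)
    return PrecisionModel(
        omega1=omega1,
        omega2=omega2,
        differential_edges=edges,
        graph_type="band",
        transform_labels=["identity"] * p,
        seed=seed,
    )


def er_precision(
    p: int,
    connect_prob: float = 0.05,
    flip_frac: float = 0.05,
    seed: int = 0,
    max_tries: int = 100,
) -> PrecisionModel:
    """Erdos-Renyi precision pair with weight magnitudes in [0.05, 0.1].

    Edge weights are drawn uniformly on +/-[1/4, 1/2] and shrunk by 5 with a
    unit diagonal; if a realization draws no edges the next substream is
    used.  Should sign flips push an eigenvalue below zero, |lambda_min| +
    0.05 is added to both diagonals (same remedy as the band graph).
    """
    if p < 3:
        raise ValueError("ER graph requires p >= 3")
    if not (0.0 < connect_prob < 1.0 and 0.0 <= flip_frac < 1.0):
        raise ValueError("probabilities out of range")
    for attempt in range(max_tries):
        rng = np.random.default_rng([seed, attempt])
        iu = np.triu_indices(p, k=1)
        present = rng.random(iu[0].size) < connect_prob
        if not present.any():
            continue
        signs = rng.choice([-1.0, 1.0], size=iu[0].size)
        mags = rng.uniform(0.25, 0.5, size=iu[0].size)
        weights = np.where(present, signs * mags / 5.0, 0.0)
        omega1 = np.zeros((p, p))
        omega1[iu] = weights
        omega1 = omega1 + omega1.T + np.eye(p)

        edge_pos = np.flatnonzero(present)
        n_flip = int(round(flip_frac * edge_pos.size))
        flip_pos = rng.choice(edge_pos, size=n_flip, replace=False) if n_flip else []
        omega2 = omega1.copy()
        edges = set()
        for pos in flip_pos:
            i, j = int(iu[0][pos]), int(iu[1][pos])
            omega2[i, j] *= -1.0
            omega2[j, i] *= -1.0
            edges.add((i, j))
        lmin = min(np.linalg.eigvalsh(omega1)[0], np.linalg.eigvalsh(omega2)[0])
        if lmin <= 0:
            shift = abs(lmin) + 0.05
            omega1 = omega1 + shift * np.eye(p)
            omega2 = omega2 + shift * np.eye(p)
        return PrecisionModel(
            omega1=omega1,
            omega2=omega2,
            differential_edges=edges,
            graph_type="er",
            transform_labels=["identity"] * p,
            seed=seed,
        )
    raise RuntimeError("could not generate a nonempty ER graph")


def sample_nonparanormal(
    model: PrecisionModel,
    n: int,
    class_index: int,
    transforms: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[ObservedMatrix, np.ndarray]:
    """Draw n observations from the nonparanormal model of one class.

    Returns the observed matrix (after marginal transforms) together with
    the latent Gaussian draw, so oracle-data and imputed-data pipelines can
    be run on the same realization.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if class_index not in (1, 2):
        raise ValueError("class_index must be 1 or 2")
    omega = model.omega1 if class_index == 1 else model.omega2
    eigs = np.linalg.eigvalsh(omega)
    if eigs[0] <= 0:
        raise ValueError("precision matrix is not positive definite")
    labels = list(transforms) if transforms is not None else list(model.transform_labels)
    if len(labels) != model.p:
        raise ValueError("need one transform label per variable")
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(omega)
    latent = rng.multivariate_normal(np.zeros(model.p), cov, size=n, method="cholesky")
    observed = np.column_stack(
        [TRANSFORMS[labels[j]](latent[:, j]) for j in range(model.p)]
    )
    obs = ObservedMatrix(values=observed, class_label=f"class{class_index}")
    return obs, latent


def _score(rejected: set[tuple[int, int]], truth: set[tuple[int, int]]) -> tuple[float, float]:
    truth_norm = {tuple(sorted(e)) for e in truth}
    rej_norm = {tuple(sorted(e)) for e in rejected}
    fp = len(rej_norm - truth_norm)
    tp = len(rej_norm & truth_norm)
    fdp = fp / max(len(rej_norm), 1)
    tpr = tp / len(truth_norm) if truth_norm else 0.0
    return fdp, tpr


def evaluate_performance(
    model: PrecisionModel,
    n1: int,
    n2: int,
    alpha_grid: Sequence[float] | None = None,
    reps: int = 10,
    config: RunConfig | None = None,
    seed: int = 0,
    transforms: Sequence[str] | None = None,
) -> PerformanceReport:
    """Average empirical FDR and power of the test over replicates.

    Per replicate both classes are sampled, the T matrix is computed once,
    and the FDR threshold is applied at every level of the alpha grid.
    FDP = FP / max(R, 1); power = TP / #differential edges.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    alpha_grid = list(alpha_grid) if alpha_grid is not None else [
        round(a, 2) for a in np.arange(0.05, 0.501, 0.05)
    ]
    config = config or RunConfig()
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(reps)
    fdp = np.zeros((reps, len(alpha_grid)))
    tpr = np.zeros((reps, len(alpha_grid)))
    for r in range(reps):
        s1, s2 = rep_seeds[r].spawn(2)
        obs1, _ = sample_nonparanormal(model, n1, 1, transforms=transforms, seed=s1)
        obs2, _ = sample_nonparanormal(model, n2, 2, transforms=transforms, seed=s2)
        T, _, _ = t_statistics([obs1, obs2], config)
        for a_idx, alpha in enumerate(alpha_grid):
            _, rejected, _ = fdr_threshold(T, alpha)
            fdp[r, a_idx], tpr[r, a_idx] = _score(rejected, model.differential_edges)
    return PerformanceReport(
        alpha_grid=alpha_grid,
        efdr=fdp.mean(axis=0).tolist(),
        power=tpr.mean(axis=0).tolist(),
        reps=reps,
        meta={
            "graph_type": model.graph_type,
            "p": model.p,
            "n1": n1,
            "n2": n2,
            "seed": seed,
            "n_differential": len(model.differential_edges),
            "method": config.method,
            "gram_source": config.gram_source,
        },
    )
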