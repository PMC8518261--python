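"""Penalty-parameter selection: StARS subsampling stability and the extended BIC.

StARS (Stability Approach to Regularization Selection) walks a decreasing
penalty path, refits the graphical lasso on random subsamples at every step,
and measures how often pairs of subsample graphs disagree about each edge.
The selected penalty is the least amount of regularization whose (monotonized)
total instability stays below a cut point ``beta`` — graphs that are both
sparse and reproducible under resampling.

The extended BIC adds a dimension-aware term ``4 |E| gamma log p`` to the
ordinary BIC and is used here to compare fits of similar sparsity, e.g. across
the steepness grid of the tailored method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DataMatrix, empirical_covariance, graph_from_precision, profile_log_likelihood
from .solver import DEFAULT_MAX_ITER, DEFAULT_TOL, glasso_path

__all__ = [
    "StarsConfig",
    "StarsResult",
    "stars_select",
    "ebic",
    "default_lambda_path",
    "default_subsample_size",
    "instability_from_adjacencies",
]


def default_subsample_size(n: int) -> int:
    """Subsample size b(n) = floor(10 sqrt(n)), capped at floor(0.8 n) for small n.

    The cap keeps subsamples strictly smaller than the data when
    10 sqrt(n) >= n (i.e. n <= 100), mirroring common StARS practice.
    """
    return min(int(np.floor(10.0 * np.sqrt(n))), int(np.floor(0.8 * n)))


def default_lambda_path(S: np.ndarray, n_lambda: int = 20, ratio: float = 0.1) -> np.ndarray:
    """Log-spaced decreasing penalty path from the guaranteed-empty-graph penalty.

    The largest value is ``max_offdiag |s_ij|`` — at that penalty every
    off-diagonal entry is soft-thresholded to zero — and the smallest is
    ``ratio`` times it.
    """
    S = np.asarray(S)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        raise ValueError("covariance has no off-diagonal signal; no path to build")
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


@dataclass
class StarsConfig:
    """Settings for StARS selection.

    ``beta`` is the instability budget — interpretable as the fraction of edges
    one is willing to accept as possibly wrong (default 0.05).
    """

    beta: float = 0.05
    n_subsamples: int = 20
    subsample_size: int | None = None
    lambda_path: np.ndarray | None = None
    n_lambda: int = 20
    lambda_min_ratio: float = 0.1
    seed: int = 0
    standardize: bool = True
    solver_tol: float = DEFAULT_TOL
    solver_max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must be in (0, 1)")
        if self.n_subsamples < 2:
            raise ValueError("need at least 2 subsamples")


@dataclass
class StarsResult:
    lambda_opt: float
    lambda_path: np.ndarray
    instability_path: np.ndarray          # raw total instability per lambda
    monotonized_path: np.ndarray          # running sup in decreasing-lambda order
    edge_instability: np.ndarray | None = None  # p x p, at lambda_opt
    selected_index: int = field(default=0)


def instability_from_adjacencies(adjacencies: np.ndarray) -> tuple[np.ndarray, float]:
    """Edge-wise and total instability from a stack of subsample adjacency matrices.

    ``adjacencies`` has shape (n_subsamples, p, p) with 0/1 entries.  The
    edge-wise instability is ``2 q (1 - q)`` with ``q`` the edge's selection
    frequency — the probability two independent subsample graphs disagree on
    it — and the total is its mean over all (p^2 - p)/2 pairs.
    """
    q = adjacencies.mean(axis=0)
    xi = 2.0 * q * (1.0 - q)
    p = q.shape[0]
    iu = np.triu_indices(p, k=1)
    return xi, float(xi[iu].mean())


def stars_select(data: DataMatrix, config: StarsConfig) -> StarsResult:
    """Select the graphical-lasso penalty by subsampling stability.

    Each subsample is drawn without replacement, standardized, and fitted along
    the full penalty path with warm starts.  The selected penalty is the
    smallest lambda whose monotonized total instability is at most ``beta``;
    if no path point qualifies the largest lambda is returned with a warning.
    """
    n, p = data.n, data.p
    S_full = empirical_covariance(data, standardize=config.standardize)
    path = (
        np.asarray(config.lambda_path, dtype=float)
        if config.lambda_path is not None
        else default_lambda_path(S_full, config.n_lambda, config.lambda_min_ratio)
    )
    if np.any(np.diff(path) > 0):
        path = np.sort(path)[::-1]
    b = config.subsample_size or default_subsample_size(n)
    if not 1 < b < n:
        raise ValueError(f"subsample size {b} must be in (1, n={n})")

    rng = np.random.default_rng(config.seed)
    n_lam = len(path)
    adj = np.zeros((config.n_subsamples, n_lam, p, p))
    for s in range(config.n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        sub = DataMatrix(data.values[idx], list(data.variable_names))
        S_sub = empirical_covariance(sub, standardize=config.standardize)
        fits = glasso_path(
            S_sub, path, tol=config.solver_tol, max_iter=config.solver_max_iter
        )
        for li, res in enumerate(fits):
            g = graph_from_precision(res.theta_hat)
            adj[s, li] = g.adjacency()

    instability = np.zeros(n_lam)
    edgewise = []
    for li in range(n_lam):
        xi, tot = instability_from_adjacencies(adj[:, li])
        edgewise.append(xi)
        instability[li] = tot
    monotonized = np.maximum.accumulate(instability)

    ok = np.flatnonzero(monotonized <= config.beta)
    if ok.size == 0:
        warnings.warn(
            "no penalty on the path meets the instability cut; returning the "
            "largest penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        sel = 0
    else:
        sel = int(ok[-1])  # smallest lambda (path is decreasing) still under beta
    return StarsResult(
        lambda_opt=float(path[sel]),
        lambda_path=path,
        instability_path=instability,
        monotonized_path=monotonized,
        edge_instability=edgewise[sel],
        selected_index=sel,
    )


def ebic(theta_hat: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.0,
         edge_tol: float | None = None) -> float:
    """Extended BIC of a fitted precision matrix.

    ``BIC_gamma(E) = -2 l_p(theta_hat) + |E| log n + 4 |E| gamma log p`` where
    ``|E|`` counts the inferred edges.  ``gamma = 0`` recovers the ordinary
    BIC; the likelihood is evaluated at the penalized estimate itself, not at
    a refit of the selected edge set.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    theta_hat = np.asarray(theta_hat, dtype=float)
    p = theta_hat.shape[0]
    kwargs = {} if edge_tol is None else {"tol": edge_tol}
    n_edges = graph_from_precision(theta_hat, **kwargs).n_edges
    ll = profile_log_likelihood(theta_hat, S, n)
    return -2.0 * ll + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)
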