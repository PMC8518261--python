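"""The tailored graphical lasso.

The weighted graphical lasso uses a prior weight matrix ``W`` (edge
confidences in [0, 1], typically absolute partial correlations estimated from
a related data set) naively: penalties ``lam * (1 - w_ij)`` trust the prior
regardless of whether the data support it.  The tailored graphical lasso
instead passes the weights through a logistic transform

    g_k(w) = 1 / (1 + exp(-k (w - w0)))

whose steepness ``k`` is chosen by the data.  ``k = 0`` flattens all weights
to 0.5 — the unweighted graphical lasso — while large ``k`` turns the
transform into a step at the midpoint ``w0``, sharply separating trusted from
untrusted edges.  The selected ``k`` is therefore a usefulness score for the
prior.  Two rules make the grid search over ``k`` well-posed:

* the sigmoid midpoint ``w0`` is the lower ``beta``-quantile of the non-zero
  prior weights, tying the threshold to the StARS instability budget ``beta``
  used when the prior weights were estimated;
* each candidate penalty matrix ``P_k = 1 - g_k(W)`` is rescaled to the same
  total penalty budget as the unweighted fit, ``lam_k ||P_k||_1 = lam p^2``,
  so the candidates have comparable sparsity and a single eBIC pass can rank
  them without re-running StARS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DataMatrix,
    empirical_covariance,
    graph_from_precision,
    partial_correlations,
)
from .selection import StarsConfig, StarsResult, ebic, stars_select
from .solver import PenaltyMatrix, SolverResult, solve_glasso, solve_wglasso

__all__ = [
    "PriorWeights",
    "TailoredResult",
    "logistic_transform",
    "choose_w0",
    "preserve_penalty",
    "default_k_grid",
    "tailored_fit",
    "weighted_glasso_fit",
    "weights_from_prior_data",
]

DEFAULT_K_MAX = 80.0
DEFAULT_K_STEPS = 41


@dataclass
class PriorWeights:
    """Symmetric matrix of prior edge confidences in [0, 1] with zero diagonal."""

    W: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("prior weight matrix must be square")
        if np.max(np.abs(self.W - self.W.T)) > 1e-8:
            raise ValueError("prior weight matrix must be symmetric")
        self.W = 0.5 * (self.W + self.W.T)
        if self.W.min() < -1e-12 or self.W.max() > 1.0 + 1e-12:
            raise ValueError("prior weights must lie in [0, 1]")
        if np.any(np.abs(np.diag(self.W)) > 1e-12):
            raise ValueError("prior weight matrix must have a zero diagonal")
        np.fill_diagonal(self.W, 0.0)

    @property
    def p(self) -> int:
        return self.W.shape[0]


@dataclass
class TailoredResult:
    """Outcome of the tailored graphical lasso grid search."""

    k_opt: float
    lambda_: float          # StARS-selected penalty for the unweighted problem
    lambda_k: float         # budget-preserving penalty scale at k_opt
    w0: float
    penalty_matrix: PenaltyMatrix
    theta_hat: np.ndarray
    solver_result: SolverResult
    k_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    ebic_path: np.ndarray = field(default_factory=lambda: np.array([]))
    stars_result: StarsResult | None = None
    target_n_edges: int | None = None
    adjusted: bool = False


def logistic_transform(W: PriorWeights | np.ndarray, k: float, w0: float) -> np.ndarray:
    """Elementwise logistic ``g_k(w) = 1 / (1 + exp(-k (w - w0)))``.

    Applied to all p^2 entries, diagonal included (prior weights have a zero
    diagonal, which transforms like any other weight).  ``k = 0`` maps every
    entry to 0.5.  ``w0 = 1`` is allowed for the degenerate binary-prior case
    where the quantile rule lands on the largest weight.
    """
    if k < 0:
        raise ValueError("steepness k must be non-negative")
    if not 0.0 < w0 <= 1.0:
        raise ValueError("sigmoid midpoint w0 must be in (0, 1]")
    Wv = W.W if isinstance(W, PriorWeights) else np.asarray(W, dtype=float)
    # guard exp overflow for very steep k; the limit is the step function
    z = np.clip(-k * (Wv - w0), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def choose_w0(W: PriorWeights | np.ndarray, beta: float = 0.05) -> float:
    """Lower ``beta``-quantile of the strictly positive prior weights.

    Uses the lower empirical quantile (inverted CDF): the smallest observed
    weight whose cumulative frequency reaches ``beta``.  With the weights
    coming from a StARS-tuned prior fit, up to a fraction ``beta`` of the
    prior's edges may be wrong — the midpoint discounts exactly that fraction.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must be in (0, 1]")
    Wv = W.W if isinstance(W, PriorWeights) else np.asarray(W, dtype=float)
    iu = np.triu_indices(Wv.shape[0], k=1)
    vals = Wv[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError(
            "prior weight matrix has no non-zero entries; use the unweighted "
            "graphical lasso instead"
        )
    return float(np.quantile(vals, beta, method="inverted_cdf"))


def preserve_penalty(lam: float, P_k: np.ndarray, p: int) -> float:
    """Budget-preserving penalty scale ``lam_k = lam p^2 / ||P_k||_1``.

    ``||P_k||_1`` is the entrywise sum of absolute values over all p^2
    entries, so that ``lam_k ||P_k||_1 = lam p^2`` — the total penalty the
    unweighted problem would spend with the all-ones penalty matrix.
    """
    norm = float(np.abs(P_k).sum())
    if norm <= 0:
        raise ValueError("penalty matrix has zero entrywise norm")
    return lam * p * p / norm


def default_k_grid(k_max: float = DEFAULT_K_MAX, k_steps: int = DEFAULT_K_STEPS) -> np.ndarray:
    """Uniform steepness grid on [0, k_max]; the logistic saturates to a step
    function well before k = 80, so finer grids buy little."""
    return np.linspace(0.0, k_max, k_steps)


def _solve_at_k(S, W, k, w0, lam, p, tol, max_iter, warm=None):
    P_k = 1.0 - logistic_transform(W, k, w0)
    lam_k = preserve_penalty(lam, P_k, p)
    penalty = PenaltyMatrix(P_k, lam_k)
    res = solve_wglasso(S, penalty, tol=tol, max_iter=max_iter,
                        warm_start=warm, validate=False)
    return P_k, lam_k, penalty, res


def tailored_fit(
    data: DataMatrix,
    W: PriorWeights,
    k_grid: np.ndarray | None = None,
    gamma: float = 0.0,
    stars_config: StarsConfig | None = None,
    adjust_sparsity: bool = True,
    lambda_: float | None = None,
    target_n_edges: int | None = None,
    solver_tol: float = 1e-4,
    solver_max_iter: int = 100,
    standardize: bool = True,
) -> TailoredResult:
    """Fit the tailored graphical lasso.

    Steps: (1) select the unweighted penalty ``lam`` by StARS (or accept a
    precomputed ``lambda_``); (2) set the sigmoid midpoint ``w0`` from the
    prior weights with the same ``beta``; (3) for each ``k`` on the grid build
    ``P_k = 1 - g_k(W)``, rescale to the common penalty budget, solve the
    weighted problem and score it with the eBIC; (4) keep the ``k`` with the
    smallest score (ties go to the smaller ``k``); (5) optionally nudge the
    final penalty scale so the fitted graph has exactly as many edges as the
    StARS-selected unweighted graph.
    """
    if W.p != data.p:
        raise ValueError(f"prior weights are {W.p}x{W.p} but data has p={data.p}")
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size == 0:
        raise ValueError("k grid is empty")
    if stars_config is None:
        stars_config = StarsConfig()

    S = empirical_covariance(data, standardize=standardize)
    p, n = data.p, data.n

    stars_result = None
    if lambda_ is None:
        stars_result = stars_select(data, stars_config)
        lambda_ = stars_result.lambda_opt
    w0 = choose_w0(W, stars_config.beta)

    if target_n_edges is None and adjust_sparsity:
        unweighted = solve_glasso(S, lambda_, tol=solver_tol,
                                  max_iter=solver_max_iter, validate=False)
        target_n_edges = graph_from_precision(unweighted.theta_hat).n_edges

    scores = np.empty(k_grid.size)
    fits: list[tuple[np.ndarray, float, PenaltyMatrix, SolverResult]] = []
    warm = None
    for i, k in enumerate(k_grid):
        P_k, lam_k, penalty, res = _solve_at_k(
            S, W, float(k), w0, lambda_, p, solver_tol, solver_max_iter, warm=warm
        )
        scores[i] = ebic(res.theta_hat, S, n, gamma)
        fits.append((P_k, lam_k, penalty, res))
        warm = res

    best = int(np.argmin(scores))  # argmin takes the first (smallest k) on ties
    k_opt = float(k_grid[best])
    P_k, lam_k, penalty, res = fits[best]

    adjusted = False
    if adjust_sparsity and target_n_edges is not None:
        res2, lam_k2, penalty2 = _adjust_to_edge_count(
            S, P_k, lam_k, target_n_edges, solver_tol, solver_max_iter, warm=res
        )
        if res2 is not None:
            res, lam_k, penalty = res2, lam_k2, penalty2
            adjusted = True

    return TailoredResult(
        k_opt=k_opt,
        lambda_=float(lambda_),
        lambda_k=float(lam_k),
        w0=w0,
        penalty_matrix=penalty,
        theta_hat=res.theta_hat,
        solver_result=res,
        k_grid=k_grid,
        ebic_path=scores,
        stars_result=stars_result,
        target_n_edges=target_n_edges,
        adjusted=adjusted,
    )


def _adjust_to_edge_count(S, P_k, lam_k, target, tol, max_iter, warm=None,
                          max_bisect=50, max_factor=4.0):
    """Bisection on a multiplicative factor for lam_k to match an edge count.

    The adjustment is meant to be slight, so the factor is confined to
    [1/max_factor, max_factor].  The edge count is non-increasing in the
    factor, but it is a step function, so an exact match may be unattainable
    (also when the target lies outside the confined range); the closest factor
    evaluated is returned then, ties going to the sparser fit.
    """
    def fit(factor, warm):
        penalty = PenaltyMatrix(P_k, lam_k * factor)
        res = solve_wglasso(S, penalty, tol=tol, max_iter=max_iter,
                            warm_start=warm, validate=False)
        count = graph_from_precision(res.theta_hat).n_edges
        return res, penalty, count

    res0, pen0, count0 = fit(1.0, warm)
    if count0 == target:
        return res0, lam_k, pen0
    evaluated = [(1.0, res0, pen0, count0)]
    # bracket: larger factor -> fewer edges
    lo, hi = 1.0, 1.0
    if count0 > target:
        while evaluated[-1][3] > target and hi < max_factor:
            hi = min(2.0 * hi, max_factor)
            evaluated.append((hi, *fit(hi, evaluated[-1][1])))
        lo = max(hi / 2.0, 1.0)
    else:
        while evaluated[-1][3] < target and lo > 1.0 / max_factor:
            lo = max(lo / 2.0, 1.0 / max_factor)
            evaluated.append((lo, *fit(lo, evaluated[-1][1])))
        hi = min(lo * 2.0, 1.0)
    for _ in range(max_bisect):
        if evaluated[-1][3] == target:
            break
        mid = 0.5 * (lo + hi)
        entry = (mid, *fit(mid, evaluated[-1][1]))
        evaluated.append(entry)
        if entry[3] > target:
            lo = mid
        elif entry[3] < target:
            hi = mid
        else:
            break
    # closest match; ties -> fewer edges (the more conservative graph)
    factor, res, pen, count = min(
        evaluated, key=lambda e: (abs(e[3] - target), e[3])
    )
    if count != target:
        warnings.warn(
            f"sparsity adjustment reached {count} edges (target {target})",
            RuntimeWarning,
            stacklevel=2,
        )
    return res, lam_k * factor, pen


def weighted_glasso_fit(
    data: DataMatrix,
    W: PriorWeights,
    stars_config: StarsConfig | None = None,
    lambda_: float | None = None,
    solver_tol: float = 1e-4,
    solver_max_iter: int = 100,
    standardize: bool = True,
) -> tuple[SolverResult, PenaltyMatrix]:
    """Plain weighted graphical lasso with ``P = 1 - W`` under the same
    penalty-budget preservation rule as the tailored method.

    This is the naive-prior comparator: weights enter untransformed, so a
    misleading prior directly distorts the penalties.
    """
    if W.p != data.p:
        raise ValueError("prior weights and data dimensions disagree")
    if stars_config is None:
        stars_config = StarsConfig()
    S = empirical_covariance(data, standardize=standardize)
    if lambda_ is None:
        lambda_ = stars_select(data, stars_config).lambda_opt
    P = 1.0 - W.W  # diagonal of W is 0, so diag(P) = 1 as in the unweighted case
    lam_w = preserve_penalty(lambda_, P, data.p)
    penalty = PenaltyMatrix(P, lam_w)
    res = solve_wglasso(S, penalty, tol=solver_tol, max_iter=solver_max_iter,
                        validate=False)
    return res, penalty


def weights_from_prior_data(
    prior_data: DataMatrix,
    stars_config: StarsConfig | None = None,
    p_expected: int | None = None,
    solver_tol: float = 1e-4,
    solver_max_iter: int = 100,
) -> PriorWeights:
    """Prior weights from a related data set: ``W = |partial correlations|`` of
    its StARS-tuned graphical lasso estimate, with zero diagonal."""
    if p_expected is not None and prior_data.p != p_expected:
        raise ValueError(
            f"prior data has {prior_data.p} variables, expected {p_expected}"
        )
    if stars_config is None:
        stars_config = StarsConfig()
    S_prior = empirical_covariance(prior_data, standardize=stars_config.standardize)
    lam = stars_select(prior_data, stars_config).lambda_opt
    fit = solve_glasso(S_prior, lam, tol=solver_tol, max_iter=solver_max_iter,
                       validate=False)
    W = np.abs(partial_correlations(fit.theta_hat))
    np.fill_diagonal(W, 0.0)
    W = np.clip(W, 0.0, 1.0)
    return PriorWeights(W, provenance="abs partial correlations of prior-data glasso fit")
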