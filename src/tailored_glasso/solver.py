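"""Graphical lasso and weighted graphical lasso solvers.

Both estimators maximize the penalized Gaussian log-likelihood

    log det(Theta) - tr(S Theta) - lam * || P o Theta ||_1

over positive-definite matrices, where ``o`` is the elementwise product.  The
unweighted graphical lasso is the special case ``P = 1`` (all-ones); the
weighted variant takes ``P = 1 - W`` for a prior weight matrix ``W`` so that
high-confidence edges are penalized less.  The L1 norm runs over all p^2
entries, diagonal included, by default — this keeps the tailored method's
penalty-budget bookkeeping exact (see :mod:`tailored_glasso.tailored`) — and
can be disabled with ``penalize_diagonal=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._cd import recover_theta, wglasso_cd
from .core import _chol_logdet

__all__ = [
    "PenaltyMatrix",
    "SolverResult",
    "solve_wglasso",
    "solve_glasso",
    "glasso_path",
    "kkt_residual",
]

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100
_INNER_MAX_SWEEPS = 200


@dataclass
class PenaltyMatrix:
    """An elementwise penalty: effective penalty on entry (i, j) is ``lam * P[i, j]``.

    ``P`` is symmetric with entries in [0, 1]; ``lam >= 0`` is the common scale.
    """

    P: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("penalty matrix must be square")
        if np.max(np.abs(self.P - self.P.T)) > 1e-8:
            raise ValueError("penalty matrix must be symmetric")
        if self.P.min() < -1e-12 or self.P.max() > 1.0 + 1e-12:
            raise ValueError("penalty matrix entries must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")

    def elementwise(self, penalize_diagonal: bool = True) -> np.ndarray:
        R = self.lam * 0.5 * (self.P + self.P.T)
        if not penalize_diagonal:
            np.fill_diagonal(R, 0.0)
        return R


@dataclass
class SolverResult:
    """Solution of a (weighted) graphical lasso problem."""

    theta_hat: np.ndarray
    sigma_hat: np.ndarray
    objective: float
    iterations: int
    converged: bool
    #: per-column lasso coefficients, kept for warm starts
    coef_: np.ndarray | None = None


def _check_covariance(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if np.max(np.abs(S - S.T)) > 1e-8:
        raise ValueError("covariance must be symmetric")
    S = 0.5 * (S + S.T)
    evals = np.linalg.eigvalsh(S)
    scale = max(np.abs(evals).max(), 1.0)
    if evals[0] < -1e-8 * scale:
        raise ValueError(
            f"covariance has negative eigenvalue {evals[0]:.3e} beyond tolerance"
        )
    return S


def _objective(theta: np.ndarray, S: np.ndarray, R: np.ndarray) -> float:
    return (
        _chol_logdet(theta)
        - float(np.sum(S * theta))
        - float(np.sum(R * np.abs(theta)))
    )


def solve_wglasso(
    S: np.ndarray,
    penalty: PenaltyMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    penalize_diagonal: bool = True,
    warm_start: SolverResult | None = None,
    validate: bool = True,
) -> SolverResult:
    """Solve the weighted graphical lasso with elementwise penalties ``lam * p_ij``.

    Entries facing a penalty larger than the corresponding covariance signal
    come out exactly zero (soft-threshold zeros); entries with ``p_ij = 0`` are
    unpenalized and effectively always kept.  Non-convergence within
    ``max_iter`` outer sweeps yields a warning and ``converged=False``, never a
    silent wrong answer.
    """
    S = _check_covariance(S) if validate else np.asarray(S, dtype=float)
    p = S.shape[0]
    if penalty.P.shape != S.shape:
        raise ValueError("penalty and covariance dimensions disagree")
    R = penalty.elementwise(penalize_diagonal)

    if p == 1:
        s = S[0, 0] + R[0, 0]
        theta = np.array([[1.0 / s]])
        return SolverResult(theta, np.array([[s]]), _objective(theta, S, R), 0, True,
                            coef_=np.zeros((1, 1)))

    if warm_start is not None and warm_start.coef_ is not None:
        W = warm_start.sigma_hat.copy()
        B = warm_start.coef_.copy()
    else:
        W = S.copy()
        B = np.zeros((p, p))

    iterations, converged = wglasso_cd(S, R, W, B, tol, max_iter, _INNER_MAX_SWEEPS)
    if not converged:
        warnings.warn(
            f"weighted graphical lasso did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    theta = recover_theta(W, B)
    return SolverResult(
        theta_hat=theta,
        sigma_hat=W,
        objective=_objective(theta, S, R),
        iterations=iterations,
        converged=converged,
        coef_=B,
    )


def solve_glasso(
    S: np.ndarray,
    lam: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    penalize_diagonal: bool = True,
    warm_start: SolverResult | None = None,
    validate: bool = True,
) -> SolverResult:
    """Unweighted graphical lasso: scalar penalty ``lam`` on every entry."""
    S = np.asarray(S, dtype=float)
    penalty = PenaltyMatrix(np.ones_like(S), lam)
    return solve_wglasso(
        S, penalty, tol=tol, max_iter=max_iter,
        penalize_diagonal=penalize_diagonal, warm_start=warm_start,
        validate=validate,
    )


def glasso_path(
    S: np.ndarray,
    lambdas: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    penalize_diagonal: bool = True,
) -> list[SolverResult]:
    """Fit the unweighted graphical lasso along a penalty path with warm starts.

    ``lambdas`` is traversed from largest to smallest (the sparse end first),
    each solution seeding the next; results are returned in the order given.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    order = np.argsort(lambdas)[::-1]
    results: dict[int, SolverResult] = {}
    prev: SolverResult | None = None
    for idx in order:
        res = solve_glasso(
            S, float(lambdas[idx]), tol=tol, max_iter=max_iter,
            penalize_diagonal=penalize_diagonal, warm_start=prev, validate=False,
        )
        results[int(idx)] = res
        prev = res
    return [results[i] for i in range(len(lambdas))]


def kkt_residual(
    result: SolverResult,
    S: np.ndarray,
    penalty: PenaltyMatrix,
    penalize_diagonal: bool = True,
    zero_tol: float = 0.0,
) -> float:
    """Maximum violation of the stationarity conditions at the fitted solution.

    For nonzero entries the condition ``sigma_ij - s_ij = lam p_ij sign(theta_ij)``
    must hold; for zero entries ``|sigma_ij - s_ij| <= lam p_ij``.  The returned
    residual is 0 for an exact solution and bounded by a small multiple of the
    convergence tolerance for a converged one.
    """
    S = np.asarray(S, dtype=float)
    R = penalty.elementwise(penalize_diagonal)
    theta = result.theta_hat
    sigma = result.sigma_hat
    diff = sigma - S
    nonzero = np.abs(theta) > zero_tol
    viol_nz = np.abs(diff - R * np.sign(theta))[nonzero]
    viol_z = np.maximum(np.abs(diff) - R, 0.0)[~nonzero]
    worst = 0.0
    if viol_nz.size:
        worst = max(worst, float(viol_nz.max()))
    if viol_z.size:
        worst = max(worst, float(viol_z.max()))
    return worst
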