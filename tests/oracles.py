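"""Independent oracles for cross-checking the coordinate-descent solver.

The ADMM solver here shares no code or algorithmic structure with the
block coordinate-descent implementation under test: it alternates an
eigendecomposition-based proximal step for the log-det term with elementwise
soft-thresholding, and converges to the same unique optimum of the convex
problem.  Slow but trustworthy on small instances.
"""

from __future__ import annotations

import numpy as np


def admm_wglasso(
    S: np.ndarray,
    R: np.ndarray,
    rho: float = 1.0,
    n_iter: int = 20_000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimize -log det(Theta) + tr(S Theta) + ||R o Theta||_1 by ADMM.

    ``R`` is the full elementwise penalty matrix (including the diagonal if it
    is to be penalized).  Returns the consensus variable after convergence.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(n_iter):
        # proximal step for -logdet + tr(S .): eigen-decompose rho(Z - U) - S
        M = rho * (Z - U) - S
        w, V = np.linalg.eigh(M)
        d = (w + np.sqrt(w**2 + 4.0 * rho)) / (2.0 * rho)
        theta = (V * d) @ V.T
        A = theta + U
        Z_new = np.sign(A) * np.maximum(np.abs(A) - R / rho, 0.0)
        primal = float(np.abs(theta - Z_new).max())
        dual = float(np.abs(rho * (Z_new - Z)).max())
        Z = Z_new
        U = U + theta - Z
        if primal < tol and dual < tol:
            break
    return Z


def wglasso_objective(theta: np.ndarray, S: np.ndarray, R: np.ndarray) -> float:
    """log det(Theta) - tr(S Theta) - ||R o Theta||_1 (the maximized objective)."""
    sign, logdet = np.linalg.slogdet(theta)
    assert sign > 0
    return float(logdet - np.sum(S * theta) - np.sum(R * np.abs(theta)))


def glasso_p2_closed_form(s: float, rho: float, diag_penalty: float = 0.0):
    """Exact 2x2 graphical-lasso solution for S = [[1, s], [s, 1]].

    The estimated covariance has diagonal 1 + diag_penalty and off-diagonal
    soft-thresholded at rho; the precision matrix is its inverse.
    """
    off = np.sign(s) * max(abs(s) - rho, 0.0)
    d = 1.0 + diag_penalty
    sigma = np.array([[d, off], [off, d]])
    return np.linalg.inv(sigma), sigma
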