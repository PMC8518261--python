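"""Numba kernels for the block coordinate-descent graphical lasso.

The solver follows the classic scheme: cycle over columns of the working
covariance ``W``, solve each column's lasso subproblem by coordinate descent
with per-element penalties ``r_ij``, and plug the fitted column back in.  A
running product ``c = W11 @ beta`` keeps every coordinate update O(1) apart
from the O(p) refresh when a coefficient actually moves, which is what makes
the dense-path workloads (StARS subsampling, the steepness grid) affordable.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def wglasso_cd(S, R, W, B, tol, max_iter, inner_max_sweeps):
    """Run block coordinate descent in place on (W, B).

    Parameters
    ----------
    S, R : (p, p) arrays — covariance and elementwise penalty (lam * p_ij).
    W, B : (p, p) arrays, modified in place — working covariance estimate and
        per-column lasso coefficients (B[:, j] are column j's coefficients,
        B[j, j] stays 0).  Pass W = S.copy(), B = 0 for a cold start or the
        previous solution for a warm start.
    tol : convergence threshold on the mean absolute change of off-diagonal W
        entries per sweep, relative to the mean absolute off-diagonal of S.
    max_iter : maximum outer sweeps.
    inner_max_sweeps : cap on coordinate-descent sweeps per column.

    Returns
    -------
    (iterations, converged)
    """
    p = S.shape[0]
    for i in range(p):
        W[i, i] = S[i, i] + R[i, i]

    off_mean = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off_mean += abs(S[i, j])
                cnt += 1
    if cnt > 0:
        off_mean /= cnt
    if off_mean <= 0.0:
        off_mean = 1.0
    thr = tol * off_mean
    inner_thr = 0.1 * thr

    converged = False
    it = 0
    c = np.zeros(p)
    for it in range(1, max_iter + 1):
        delta = 0.0
        for j in range(p):
            # c <- W[:, active] @ B[active, j], skipping the j block
            for i in range(p):
                c[i] = 0.0
            for l in range(p):
                bl = B[l, j]
                if bl != 0.0 and l != j:
                    for i in range(p):
                        c[i] += W[i, l] * bl
            for _sweep in range(inner_max_sweeps):
                dmax = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    bi = B[i, j]
                    z = S[i, j] - (c[i] - W[i, i] * bi)
                    r = R[i, j]
                    if z > r:
                        bnew = (z - r) / W[i, i]
                    elif z < -r:
                        bnew = (z + r) / W[i, i]
                    else:
                        bnew = 0.0
                    db = bnew - bi
                    if db != 0.0:
                        B[i, j] = bnew
                        for l in range(p):
                            c[l] += W[l, i] * db
                        if abs(db) > dmax:
                            dmax = abs(db)
                if dmax < inner_thr:
                    break
            for i in range(p):
                if i != j:
                    d = c[i] - W[i, j]
                    delta += abs(d)
                    W[i, j] = c[i]
                    W[j, i] = c[i]
        delta /= p * (p - 1) if p > 1 else 1
        if delta < thr:
            converged = True
            break
    return it, converged


@njit(cache=True)
def recover_theta(W, B):
    """Reconstruct the precision matrix from the working covariance and coefficients.

    Uses the block-inverse identities theta_jj = 1/(w_jj - w12' beta) and
    theta_12 = -beta * theta_jj.  Off-diagonal entries are averaged across the
    two column solves; an exact zero on either side is kept as an exact zero so
    the soft-threshold sparsity pattern survives.
    """
    p = W.shape[0]
    T = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for i in range(p):
            if i != j:
                dot += W[i, j] * B[i, j]
        tjj = 1.0 / (W[j, j] - dot)
        T[j, j] = tjj
        for i in range(p):
            if i != j:
                T[i, j] = -B[i, j] * tjj
    for j in range(p):
        for i in range(j):
            a = T[i, j]
            b = T[j, i]
            if a == 0.0 or b == 0.0:
                T[i, j] = 0.0
                T[j, i] = 0.0
            else:
                m = 0.5 * (a + b)
                T[i, j] = m
                T[j, i] = m
    return T
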