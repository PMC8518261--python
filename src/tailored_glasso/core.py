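"""Core quantities of Gaussian graphical models.

A Gaussian graphical model (GGM) encodes conditional-independence structure
among jointly Gaussian variables through the zero pattern of the precision
matrix ``Theta = Sigma^{-1}``: variables *i* and *j* are conditionally
independent given all others exactly when ``theta_ij = 0``.  This module
collects the deterministic formulas every estimator in the package shares —
the empirical covariance, partial correlations, the profile log-likelihood,
edge extraction and the sparsity measure — together with the light container
types they operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataMatrix",
    "GraphStructure",
    "empirical_covariance",
    "partial_correlations",
    "profile_log_likelihood",
    "graph_from_precision",
    "sparsity",
]

#: Default numerical-zero threshold applied to solver output when reading off
#: edges.  The coordinate-descent solver produces exact soft-threshold zeros,
#: but reconstruction of Theta from the regression coefficients can leave
#: float residue of this order.
EDGE_TOL = 1e-10


@dataclass
class DataMatrix:
    """An ``n x p`` matrix of observations (rows = samples, columns = variables).

    Variables are assumed approximately Gaussian after column standardization.
    Missing values are not allowed.
    """

    values: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("data matrix must be two-dimensional")
        if np.isnan(self.values).any():
            raise ValueError("data matrix contains missing values (NaN)")
        if not self.variable_names:
            self.variable_names = [f"V{j + 1}" for j in range(self.p)]
        if len(self.variable_names) != self.p:
            raise ValueError(
                f"{len(self.variable_names)} variable names for {self.p} columns"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "DataMatrix":
        """Return a copy with each column centered to mean 0 and scaled to sd 1.

        Standard deviations use the 1/n convention, matching
        :func:`empirical_covariance`, so the standardized covariance has unit
        diagonal exactly.
        """
        sd = self.values.std(axis=0)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            raise ValueError(
                f"zero-variance column(s): {[self.variable_names[j] for j in bad]}; "
                "remove constant variables before fitting"
            )
        centered = self.values - self.values.mean(axis=0)
        return DataMatrix(centered / sd, list(self.variable_names))


@dataclass
class GraphStructure:
    """An undirected, unweighted graph over ``p`` labeled nodes.

    Edges are unordered index pairs ``(i, j)`` with ``i < j``; self-loops are
    rejected.
    """

    p: int
    edges: frozenset
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < self.p and 0 <= j < self.p):
                raise ValueError(f"edge ({i}, {j}) outside node range 0..{self.p - 1}")
            canon.add((min(i, j), max(i, j)))
        self.edges = frozenset(canon)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def sparsity(self) -> float:
        return sparsity(self)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.p, self.p))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A


def empirical_covariance(data: DataMatrix, standardize: bool = True) -> np.ndarray:
    """Empirical covariance ``S = (1/n) Xc' Xc`` of (optionally standardized) data.

    The divisor-by-``n`` (maximum likelihood) convention is used throughout so
    that :func:`profile_log_likelihood` is the exact profile log-likelihood of
    the Gaussian model.  With ``standardize=True`` every diagonal entry is
    exactly 1.
    """
    if data.n < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    X = data.standardized().values if standardize else data.values - data.values.mean(axis=0)
    S = (X.T @ X) / data.n
    if standardize:
        np.fill_diagonal(S, 1.0)
    return 0.5 * (S + S.T)


def partial_correlations(theta: np.ndarray) -> np.ndarray:
    """Partial correlations ``rho_ij = -theta_ij / sqrt(theta_ii theta_jj)``.

    The diagonal is reported as 1 by convention.  The input must have a
    strictly positive diagonal (any positive-definite matrix qualifies).
    """
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    scale = np.sqrt(np.outer(d, d))
    rho = -theta / scale
    np.fill_diagonal(rho, 1.0)
    return 0.5 * (rho + rho.T)


def _chol_logdet(theta: np.ndarray) -> float:
    """log det via Cholesky; failure doubles as the positive-definiteness test."""
    try:
        L = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("matrix is not positive definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def profile_log_likelihood(theta: np.ndarray, S: np.ndarray, n: int) -> float:
    """Profile log-likelihood of a Gaussian model at precision matrix ``theta``.

    ``l_p(Theta) = -(np/2) log(2 pi) + (n/2) log det Theta - (n/2) tr(S Theta)``

    with ``S`` the empirical (1/n) covariance.  Maximized over positive-definite
    matrices by ``Theta = S^{-1}`` when ``S`` is invertible.
    """
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    if theta.shape != S.shape:
        raise ValueError("theta and S dimensions disagree")
    p = theta.shape[0]
    logdet = _chol_logdet(theta)
    trace = float(np.sum(S * theta))  # tr(S Theta) for symmetric S
    return -0.5 * n * p * np.log(2.0 * np.pi) + 0.5 * n * logdet - 0.5 * n * trace


def graph_from_precision(
    theta: np.ndarray,
    tol: float = EDGE_TOL,
    node_names: list[str] | None = None,
) -> GraphStructure:
    """Edge set of the conditional-independence graph: ``{i,j}`` iff ``|theta_ij| > tol``."""
    if tol < 0:
        raise ValueError("tol must be non-negative")
    theta = np.asarray(theta)
    p = theta.shape[0]
    iu = np.triu_indices(p, k=1)
    mask = np.abs(theta[iu]) > tol
    edges = frozenset(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    return GraphStructure(p=p, edges=edges, node_names=node_names)


def sparsity(graph: GraphStructure) -> float:
    """Fraction of realized edges: ``2 N_e / (p^2 - p)``."""
    if graph.p < 2:
        raise ValueError("sparsity undefined for p < 2")
    return 2.0 * graph.n_edges / (graph.p**2 - graph.p)
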