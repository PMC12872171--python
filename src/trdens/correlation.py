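"""Spatial and spatiotemporal working-correlation structures.

The spatial structure is a proper conditional autoregressive (CAR) model on
the tract adjacency graph: the precision matrix is ``Q = D - gamma * W``
where ``W`` is the (symmetric, zero-diagonal) adjacency matrix, ``D`` the
diagonal degree matrix, and ``gamma`` in (-1, 1) controls the strength of
neighbour dependence.  The implied covariance ``Q^{-1}`` is rescaled to unit
diagonal so the structure enters the marginal model purely as a correlation.

Temporal dependence across the two study years is AR(1); with two timepoints
it reduces to a single lag-one correlation ``phi``.  The joint working
correlation over tract-year rows (ordered year-major: all tracts at the
first year, then all tracts at the second) is the Kronecker product
``R_AR (x) R_space``.

Isolated tracts (degree zero) get unit variance and zero correlation with
everything, so disconnected graphs are handled without special casing by
callers.
"""

from __future__ import annotations

from functools import cached_property

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "CarStructure",
    "car_correlation",
    "ar_correlation",
    "spacetime_correlation",
    "morans_i",
]


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not abs(gamma) < 1:
        raise ValueError(f"CAR dependence parameter must satisfy |gamma| < 1, got {gamma}")
    return gamma


def _check_phi(phi: float) -> float:
    phi = float(phi)
    if not abs(phi) < 1:
        raise ValueError(f"AR correlation must satisfy |phi| < 1, got {phi}")
    return phi


class CarStructure:
    """Spectral apparatus for the proper-CAR family on one fixed graph.

    Writing ``Q(gamma) = D^{1/2} (I - gamma * B) D^{1/2}`` with the
    degree-normalised adjacency ``B = D^{-1/2} W D^{-1/2}``, a single
    eigendecomposition of ``B`` gives, for every ``gamma``, cheap access to
    marginal variances ``diag(Q^{-1})``, the log-determinant of ``Q``, a
    square-root factor of the correlation matrix, and the exact inverse of
    the correlation matrix (which is sparse up to diagonal scaling).  The
    iterative model fit and the count simulator both lean on this.

    Eigenvalues of ``B`` lie in [-1, 1], so ``Q`` is positive definite for
    every |gamma| < 1.

    Parameters
    ----------
    graph
        Undirected adjacency graph (no self-loops).
    nodes
        Node ordering defining row/column indices; defaults to sorted nodes.
    """

    def __init__(self, graph: nx.Graph, nodes=None):
        if nodes is None:
            nodes = sorted(graph.nodes)
        self.nodes = list(nodes)
        if set(self.nodes) != set(graph.nodes):
            raise ValueError("node list does not match graph nodes")
        if any(graph.has_edge(u, u) for u in graph.nodes):
            raise ValueError("adjacency graph must not contain self-loops")
        W = nx.to_scipy_sparse_array(graph, nodelist=self.nodes, format="csr", dtype=float)
        self.n = len(self.nodes)
        self.W = W
        degree = np.asarray(W.sum(axis=1)).ravel()
        # isolated tracts: unit conditional variance, no neighbours
        self.d = np.where(degree > 0, degree, 1.0)
        self._sqrt_d = np.sqrt(self.d)

    @cached_property
    def _spectrum(self):
        dis = 1.0 / self._sqrt_d
        B = sp.diags(dis) @ self.W @ sp.diags(dis)
        lam, U = np.linalg.eigh(B.toarray())
        return lam, U, U**2

    def precision(self, gamma: float) -> sp.csr_array:
        """Sparse CAR precision ``Q = D - gamma W`` (unit diagonal for isolated nodes)."""
        gamma = _check_gamma(gamma)
        return (sp.diags(self.d) - gamma * self.W).tocsr()

    def marginal_variances(self, gamma: float) -> np.ndarray:
        """``diag(Q(gamma)^{-1})``."""
        gamma = _check_gamma(gamma)
        if gamma == 0.0:
            return 1.0 / self.d
        lam, _, U2 = self._spectrum
        return (U2 @ (1.0 / (1.0 - gamma * lam))) / self.d

    def logdet_precision(self, gamma: float) -> float:
        gamma = _check_gamma(gamma)
        if gamma == 0.0:
            return float(np.sum(np.log(self.d)))
        lam, _, _ = self._spectrum
        return float(np.sum(np.log(self.d)) + np.sum(np.log1p(-gamma * lam)))

    def correlation(self, gamma: float) -> np.ndarray:
        """Dense spatial correlation matrix: ``Q^{-1}`` rescaled to unit diagonal."""
        gamma = _check_gamma(gamma)
        if gamma == 0.0:
            return np.eye(self.n)
        lam, U, _ = self._spectrum
        scaled = (U / self._sqrt_d[:, None]) / np.sqrt(1.0 - gamma * lam)
        cov = scaled @ scaled.T
        s = np.sqrt(np.diag(cov))
        return cov / np.outer(s, s)

    def correlation_factor(self, gamma: float) -> np.ndarray:
        """Square-root factor ``F`` with ``F F^T = R_space(gamma)``."""
        gamma = _check_gamma(gamma)
        if gamma == 0.0:
            return np.eye(self.n)
        lam, U, _ = self._spectrum
        F = (U / self._sqrt_d[:, None]) / np.sqrt(1.0 - gamma * lam)
        v = self.marginal_variances(gamma)
        return F / np.sqrt(v)[:, None]

    def correlation_inverse_parts(self, gamma: float):
        """Return ``(Q, s)`` with ``R_space^{-1} = diag(s) Q diag(s)``.

        ``Q`` is sparse, so applying the inverse correlation costs
        O(edges) per vector.
        """
        gamma = _check_gamma(gamma)
        return self.precision(gamma), np.sqrt(self.marginal_variances(gamma))

    def logdet_correlation(self, gamma: float) -> float:
        """``log |R_space(gamma)|``."""
        v = self.marginal_variances(gamma)
        return float(-self.logdet_precision(gamma) - np.sum(np.log(v)))


def car_correlation(graph: nx.Graph, gamma: float, nodes=None) -> np.ndarray:
    """Proper-CAR spatial correlation matrix on ``graph``.

    Precision ``Q = D - gamma W``; covariance ``Q^{-1}`` rescaled to unit
    diagonal.  Symmetric positive definite for |gamma| < 1; ``gamma = 0``
    gives the identity; isolated nodes get unit variance and zero
    correlation.
    """
    return CarStructure(graph, nodes=nodes).correlation(gamma)


def ar_correlation(phi: float, n_times: int = 2) -> np.ndarray:
    """AR(1) correlation matrix over equally spaced timepoints."""
    phi = _check_phi(phi)
    idx = np.arange(n_times)
    return phi ** np.abs(idx[:, None] - idx[None, :])


def spacetime_correlation(r_space: np.ndarray, phi: float, n_times: int = 2) -> np.ndarray:
    """Separable space-time working correlation ``R_AR (x) R_space``.

    Row ordering is year-major: entry for (tract i, time t) x (tract j,
    time s) equals ``r_space[i, j] * phi**|t - s|``.
    """
    r_space = np.asarray(r_space, dtype=float)
    if r_space.ndim != 2 or r_space.shape[0] != r_space.shape[1]:
        raise ValueError("r_space must be a square matrix")
    if not np.allclose(np.diag(r_space), 1.0):
        raise ValueError("r_space must have unit diagonal")
    return np.kron(ar_correlation(phi, n_times), r_space)


def morans_i(values: np.ndarray, graph: nx.Graph, nodes=None) -> float:
    """Moran's I spatial autocorrelation of ``values`` on ``graph``.

    Binary (adjacency) weights; values are centred internally.
    """
    if nodes is None:
        nodes = sorted(graph.nodes)
    W = nx.to_scipy_sparse_array(graph, nodelist=list(nodes), format="csr", dtype=float)
    x = np.asarray(values, dtype=float)
    if x.shape[0] != W.shape[0]:
        raise ValueError("values length does not match graph size")
    z = x - x.mean()
    denom = float(z @ z)
    s0 = float(W.sum())
    if denom == 0.0 or s0 == 0.0:
        return 0.0
    return float(len(z) / s0 * (z @ (W @ z)) / denom)
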