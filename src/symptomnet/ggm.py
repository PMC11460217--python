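"""Regularized Gaussian graphical model estimation with EBIC selection.

The partial-correlation network is estimated by the graphical lasso over a
log-spaced penalty grid; the model minimizing the extended Bayesian
information criterion (EBIC) is selected and its precision matrix converted
to partial correlations rho_ij = -K_ij / sqrt(K_ii K_jj).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

__all__ = [
    "SymptomNetwork",
    "GlassoPath",
    "sample_correlation",
    "glasso_fit",
    "ebic",
    "precision_to_partial",
    "select_network",
]

EDGE_TOL = 1e-10


@dataclass
class SymptomNetwork:
    """Partial-correlation network over named symptom nodes."""

    nodes: list[str]
    weights: np.ndarray  # p x p symmetric, zero diagonal
    lambda_selected: float
    gamma: float
    n_used: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weights shape must match node count")
        if np.max(np.abs(w - w.T)) > 1e-10:
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(len(self.nodes), k=1)
        return int(np.sum(np.abs(self.weights[iu]) > EDGE_TOL))

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.nodes), k=1)
        mask = np.abs(self.weights[iu]) > EDGE_TOL
        return pd.DataFrame(
            {
                "node_a": [self.nodes[i] for i in iu[0][mask]],
                "node_b": [self.nodes[j] for j in iu[1][mask]],
                "weight": self.weights[iu][mask],
            }
        )


@dataclass
class GlassoPath:
    lambdas: np.ndarray
    precisions: list[np.ndarray] = field(repr=False)
    ebics: np.ndarray = field(default=None)  # type: ignore[assignment]


def sample_correlation(transformed: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pearson correlation of the transformed data, with sanity warnings."""
    X = np.asarray(transformed, dtype=float)
    n, p = X.shape
    if np.any(X.std(axis=0) == 0):
        bad = int(np.flatnonzero(X.std(axis=0) == 0)[0])
        raise ValueError(f"constant column at position {bad}")
    if n <= p:
        warnings.warn(f"n={n} <= p={p}; correlation matrix is rank deficient", stacklevel=2)
    S = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(p, k=1)
    if np.any(np.abs(S[iu]) > 1.0 - 1e-12):
        warnings.warn("duplicated (perfectly correlated) columns detected", stacklevel=2)
    return S


def glasso_fit(S: np.ndarray, lam: float, tol: float = 1e-4, max_iter: int = 500) -> np.ndarray:
    """L1-penalized precision estimate; lam=0 reduces to plain inversion."""
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0.0:
        K = np.linalg.inv(S)
    else:
        try:
            _, K = graphical_lasso(S, alpha=float(lam), tol=tol, max_iter=max_iter)
        except FloatingPointError as exc:  # pragma: no cover - solver diagnostics
            raise RuntimeError(f"graphical lasso failed to converge at lambda={lam:g}: {exc}") from exc
    return (K + K.T) / 2.0


def ebic(K: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """EBIC of a Gaussian model: -n(log det K - tr(SK)) + |E| log n + 4|E| gamma log p."""
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    iu = np.triu_indices(p, k=1)
    n_edges = int(np.sum(np.abs(K[iu]) > EDGE_TOL))
    loglik = logdet - np.trace(S @ K)
    return float(-n * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p))


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return (P + P.T) / 2.0


def select_network(
    transformed: pd.DataFrame,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
) -> tuple[SymptomNetwork, GlassoPath]:
    """EBIC-minimizing graphical-lasso network over a log-spaced penalty grid.

    The grid runs from lambda_max (the smallest penalty yielding an empty
    graph, i.e. the largest absolute off-diagonal sample correlation) down to
    ``lambda_min_ratio * lambda_max``.
    """
    nodes = list(transformed.columns)
    X = transformed.to_numpy(dtype=float)
    n, p = X.shape
    S = sample_correlation(X)
    iu = np.triu_indices(p, k=1)
    lam_max = float(np.max(np.abs(S[iu])))
    if lam_max <= 0:
        lam_max = 1e-3
    grid = np.logspace(np.log10(lam_max), np.log10(lambda_min_ratio * lam_max), n_lambdas)
    precisions: list[np.ndarray] = []
    ebics = np.empty(n_lambdas)
    for k, lam in enumerate(grid):
        K = glasso_fit(S, lam)
        precisions.append(K)
        ebics[k] = ebic(K, S, n, gamma)
    best = int(np.argmin(ebics))
    K_best = precisions[best]
    net = SymptomNetwork(
        nodes=nodes,
        weights=precision_to_partial(K_best),
        lambda_selected=float(grid[best]),
        gamma=float(gamma),
        n_used=n,
    )
    if net.edge_count == 0:
        warnings.warn("selected network is empty (sparse/unstable input)", stacklevel=2)
    return net, GlassoPath(lambdas=grid, precisions=precisions, ebics=ebics)
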