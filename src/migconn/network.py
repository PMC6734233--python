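"""Weighted undirected connectivity networks and degree centrality.

Edges are L2-regularized partial correlations between node time series:
the sample correlation matrix is ridge-stabilized, inverted, and scaled to
partial correlations.  Edge weights are then soft-thresholded with a power
adjacency (|r|^beta, beta >= 1), variance-stabilized with Fisher's r-to-z
transform, and summarized per node as degree centrality, the sum of incident
edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NetworkParams",
    "ConnectivityMatrix",
    "partial_correlation_l2",
    "soft_threshold",
    "fisher_z",
    "degree_centrality",
    "connectivity_chain",
    "FunctionalConnectome",
]

Stage = Literal["partial_r", "soft", "fisher_z"]


@dataclass(frozen=True)
class NetworkParams:
    """Edge-construction parameters.

    ridge_lambda is expressed relative to the mean diagonal of the sample
    covariance; soft_power_beta is the power-adjacency exponent; with
    use_absolute_weights the sign of the partial correlation is discarded
    before thresholding.
    """

    ridge_lambda: float = 0.1
    soft_power_beta: float = 6.0
    use_absolute_weights: bool = True

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.soft_power_beta < 1:
            raise ValueError("soft_power_beta must be >= 1")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """K x K symmetric edge matrix with zero diagonal at a named stage."""

    edges: np.ndarray
    stage: Stage

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("edge matrix must be square")
        if not np.allclose(e, e.T, atol=1e-12):
            raise ValueError("edge matrix must be symmetric")
        if np.any(np.diag(e) != 0):
            raise ValueError("edge matrix must have a zero diagonal")
        object.__setattr__(self, "edges", e)


def _edges(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    return m.edges if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)


def partial_correlation_l2(
    node_ts: np.ndarray, ridge_lambda: float = 0.1
) -> ConnectivityMatrix:
    """Ridge-regularized partial correlation between node time series.

    Columns are standardized, the sample covariance ``S`` is stabilized as
    ``S + lambda * c * I`` (``c`` = mean diagonal of ``S``), inverted to the
    precision ``P``, and scaled: ``r_ij = -P_ij / sqrt(P_ii P_jj)``.  At
    ``lambda = 0`` this equals the correlation of residuals after regressing
    each pair of nodes on all remaining nodes.
    """
    X = np.asarray(node_ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("node time series must be a T x K array")
    T, K = X.shape
    if T <= 2 or K < 2:
        raise ValueError("need T > 2 frames and K >= 2 nodes")
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant time series at node(s) {dead.tolist()}")
    Xs = (X - X.mean(axis=0)) / sd
    S = Xs.T @ Xs / (T - 1)
    c = S.diagonal().mean()
    P = np.linalg.inv(S + ridge_lambda * c * np.eye(K))
    d = np.sqrt(np.diag(P))
    R = -P / np.outer(d, d)
    R = np.clip((R + R.T) / 2.0, -1.0 + 1e-15, 1.0 - 1e-15)
    np.fill_diagonal(R, 0.0)
    return ConnectivityMatrix(edges=R, stage="partial_r")


def soft_threshold(
    matrix: ConnectivityMatrix | np.ndarray,
    soft_power_beta: float = 6.0,
    use_absolute_weights: bool = True,
) -> ConnectivityMatrix:
    """Power-adjacency soft threshold ``w = |r|^beta`` (sign kept when
    ``use_absolute_weights`` is false).  Order-preserving on |r|."""
    if soft_power_beta < 1:
        raise ValueError("soft_power_beta must be >= 1")
    r = _edges(matrix)
    if np.any(np.abs(r) >= 1):
        raise ValueError("soft threshold expects entries in (-1, 1)")
    w = np.abs(r) ** soft_power_beta
    if not use_absolute_weights:
        w = np.sign(r) * w
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(edges=w, stage="soft")


def fisher_z(matrix: ConnectivityMatrix | np.ndarray) -> ConnectivityMatrix:
    """Elementwise Fisher r-to-z transform, ``z = arctanh(w)``."""
    w = _edges(matrix)
    if np.any(np.abs(w) >= 1):
        raise ValueError("Fisher transform requires |w| < 1")
    z = np.arctanh(w)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(edges=z, stage="fisher_z")


def degree_centrality(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Per-node degree centrality: the sum of incident edge weights."""
    z = _edges(matrix)
    if not np.allclose(z, z.T, atol=1e-12):
        raise ValueError("degree centrality requires a symmetric matrix")
    off = z.copy()
    np.fill_diagonal(off, 0.0)
    return off.sum(axis=1)


def connectivity_chain(
    node_ts: np.ndarray, params: NetworkParams = NetworkParams()
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Full edge chain partial_r -> soft -> fisher_z plus degree centrality."""
    r = partial_correlation_l2(node_ts, params.ridge_lambda)
    w = soft_threshold(r, params.soft_power_beta, params.use_absolute_weights)
    z = fisher_z(w)
    return z, degree_centrality(z)


class FunctionalConnectome(BaseEstimator, TransformerMixin):
    """Stateless transformer: node time series -> network summaries.

    ``transform`` maps each subject's T x K series to either the per-node
    degree-centrality vector (``output='degree'``, shape (n, K)) or the
    Fisher-z edge matrix (``output='matrix'``, shape (n, K, K)).  Composes
    with sklearn pipelines; ``fit`` only validates parameters.
    """

    def __init__(
        self,
        ridge_lambda: float = 0.1,
        soft_power_beta: float = 6.0,
        use_absolute_weights: bool = True,
        output: str = "degree",
    ):
        self.ridge_lambda = ridge_lambda
        self.soft_power_beta = soft_power_beta
        self.use_absolute_weights = use_absolute_weights
        self.output = output

    def _params(self) -> NetworkParams:
        return NetworkParams(
            ridge_lambda=self.ridge_lambda,
            soft_power_beta=self.soft_power_beta,
            use_absolute_weights=self.use_absolute_weights,
        )

    def fit(self, X=None, y=None) -> "FunctionalConnectome":
        if self.output not in ("degree", "matrix"):
            raise ValueError("output must be 'degree' or 'matrix'")
        self._params()
        self.n_features_in_ = None
        return self

    def transform(self, X: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
        self.fit()
        params = self._params()
        out = []
        for ts in X:
            z, dc = connectivity_chain(np.asarray(ts, float), params)
            out.append(dc if self.output == "degree" else z.edges)
        return np.stack(out)
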