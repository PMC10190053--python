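"""Accuracy metrics and diagnostics.

* average absolute error between true and estimated proportion matrices
  (bounded by 2/t_N: the worst case is two different one-hot rows),
* dominant-type accuracy,
* Moran's I spatial autocorrelation on a k-nearest-neighbour spot graph,
* pairwise Pearson co-occurrence of type proportions with significance flags,
* the Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

__all__ = [
    "average_absolute_error",
    "dominant_type_accuracy",
    "SpotGraph",
    "build_knn_graph",
    "morans_i",
    "cooccurrence_matrix",
    "gelman_rubin",
]


def _as_H(H) -> np.ndarray:
    H = np.asarray(H.values if isinstance(H, pd.DataFrame) else H, dtype=float)
    if H.ndim != 2:
        raise ValueError("proportions must be a spot x type matrix")
    return H


def average_absolute_error(H_true, H_est) -> float:
    """Mean absolute difference over all spots and types.

    epsilon = sum_ij |h_ij - hhat_ij| / (t_N * s_M), in [0, 2/t_N].
    """
    H_true, H_est = _as_H(H_true), _as_H(H_est)
    if H_true.shape != H_est.shape:
        raise ValueError(f"shape mismatch: {H_true.shape} vs {H_est.shape}")
    return float(np.abs(H_true - H_est).mean())


def dominant_type_accuracy(H_true, H_est) -> float:
    """Fraction of spots whose estimated argmax type matches the true one.

    Ties are broken toward the lowest type index, with a warning.
    """
    H_true, H_est = _as_H(H_true), _as_H(H_est)
    if H_true.shape != H_est.shape:
        raise ValueError(f"shape mismatch: {H_true.shape} vs {H_est.shape}")
    for name, H in (("true", H_true), ("estimated", H_est)):
        n_max = (H == H.max(axis=1, keepdims=True)).sum(axis=1)
        if (n_max > 1).any():
            warnings.warn(f"ties in {name} dominant types broken toward the lowest index")
    return float((H_true.argmax(axis=1) == H_est.argmax(axis=1)).mean())


@dataclass
class SpotGraph:
    """Symmetric non-negative spatial weights over spots (zero diagonal)."""

    coords: np.ndarray   # (n, 2)
    weights: np.ndarray  # (n, n)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if (W < 0).any() or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square non-negative matrix")
        if np.diagonal(W).any():
            raise ValueError("self-weights must be zero")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if W.sum() <= 0:
            raise ValueError("graph has no edges")
        self.weights = W
        self.coords = np.asarray(self.coords, dtype=float)


def build_knn_graph(coords, k: int = 6, max_distance: float | None = None) -> SpotGraph:
    """Binary symmetric k-nearest-neighbour adjacency from spot coordinates.

    k=6 matches the hexagonal neighbourhood of Visium arrays. The kNN
    relation is symmetrized by union; ``max_distance`` optionally prunes
    long edges.
    """
    coords = np.asarray(coords.values if isinstance(coords, pd.DataFrame) else coords,
                        dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two spots")
    tree = cKDTree(coords)
    k_eff = min(k + 1, n)
    dist, idx = tree.query(coords, k=k_eff)
    W = np.zeros((n, n))
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            if max_distance is not None and d > max_distance:
                continue
            W[i, j] = W[j, i] = 1.0
    return SpotGraph(coords=coords, weights=W)


def morans_i(values, graph: SpotGraph) -> float:
    """Moran's I = (n / sum_ij w_ij) * sum_ij w_ij z_i z_j / sum_i z_i^2,
    with z the centred values; in [-1, 1] for row-standardizable weights."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n != graph.weights.shape[0]:
        raise ValueError("values length must match the graph size")
    z = x - x.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("Moran's I is undefined for a constant vector")
    W = graph.weights
    return float(n / W.sum() * (z @ W @ z) / denom)


def cooccurrence_matrix(H_est, alpha: float = 0.05):
    """Pairwise Pearson correlation of type proportions across spots.

    Returns (corr, pval, significant): type x type DataFrames/mask; the
    two-sided p-value comes from the product-moment t statistic, and a pair
    is flagged significant when p <= alpha (no multiplicity correction).
    """
    if not isinstance(H_est, pd.DataFrame):
        H_est = pd.DataFrame(np.asarray(H_est, dtype=float))
    types = list(H_est.columns)
    T = len(types)
    corr = np.eye(T)
    pval = np.zeros((T, T))
    for i in range(T):
        for j in range(i + 1, T):
            r, p = pearsonr(H_est.iloc[:, i], H_est.iloc[:, j])
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    corr = pd.DataFrame(corr, index=types, columns=types)
    pval = pd.DataFrame(pval, index=types, columns=types)
    return corr, pval, pval <= alpha


def gelman_rubin(traces) -> float:
    """Potential scale reduction factor R-hat from m chains of length n.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the variance of the chain means.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    m, n = traces.shape
    if n < 2:
        raise ValueError("need >= 2 draws per chain")
    chain_means = traces.mean(axis=1)
    B_over_n = chain_means.var(ddof=1)
    W = traces.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))
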