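"""Deterministic maps and likelihood of the negative-binomial mixture model.

A spot s holds N_s cells split across t_N types in proportions h_st. Every
gene g has a base expression lambda0 in every cell and an extra marker
over-expression Lambda_gt in cells of the types it marks (B_gt = 1). A single
cell of type t therefore expresses g at rate lambda0 + B_gt * Lambda_gt, and
summing independent NB reads over the cells of a spot gives

    C_gs ~ NB( N_s * (1 - p_g) / p_g * mu_gs,  p_g ),
    mu_gs = sum_t h_st * (lambda0 + B_gt * Lambda_gt),

in the NB(r, p) convention with pmf

    P(X = k) = Gamma(k + r) / (Gamma(r) k!) * (1 - p)^r * p^k,

whose mean is r p / (1 - p) and variance r p / (1 - p)^2 (additive in r at
shared p). Note the convention differs from scipy/numpy, whose "success
probability" equals 1 - p of this model.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .data import ExpressionMatrix, MarkerMatrix

__all__ = [
    "compute_proportions",
    "compute_mu",
    "nb_rate",
    "nb_log_pmf",
    "total_log_likelihood",
    "expected_types_per_spot",
    "alpha_for_expected_types",
]


def compute_proportions(theta: np.ndarray) -> np.ndarray:
    """Normalize positive abundances theta into per-spot proportions.

    Accepts a single row (one spot) or a spot x type matrix; rows sum to 1.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0 or (theta <= 0).any() or not np.isfinite(theta).all():
        raise ValueError("abundances must be strictly positive and finite")
    total = theta.sum(axis=-1, keepdims=True)
    return theta / total


def compute_mu(H: np.ndarray, B: np.ndarray, lambda0: float, Lambda: np.ndarray) -> np.ndarray:
    """Mean single-cell expression mu_gs = sum_t h_st (lambda0 + B_gt Lambda_gt).

    ``H`` is spot x type (rows summing to 1), ``B`` and ``Lambda`` gene x type.
    Returns a gene x spot matrix. Because rows of H sum to one, lambda0 enters
    additively: mu = lambda0 + (B * Lambda) @ H.T.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    Lambda = np.atleast_2d(np.asarray(Lambda, dtype=float))
    if H.shape[1] != B.shape[1] or B.shape != Lambda.shape:
        raise ValueError(
            f"type-dimension mismatch: H {H.shape}, B {B.shape}, Lambda {Lambda.shape}"
        )
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    return lambda0 + (B * Lambda) @ H.T


def nb_rate(mu, N, p):
    """NB rate r = N * (1 - p) / p * mu; the implied mean of NB(r, p) is N * mu."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie strictly inside (0, 1)")
    return np.asarray(N, dtype=float) * (1.0 - p) / p * np.asarray(mu, dtype=float)


def nb_log_pmf(k, r, p):
    """log NB(k | r, p) with P(X=k) = Gamma(k+r)/(Gamma(r) k!) (1-p)^r p^k."""
    k = np.asarray(k)
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if (r <= 0).any():
        raise ValueError("r must be strictly positive")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie strictly inside (0, 1)")
    if (k < 0).any() or not np.issubdtype(k.dtype, np.integer) and not np.allclose(k, np.rint(k)):
        raise ValueError("k must be a non-negative integer")
    kf = k.astype(float)
    return gammaln(kf + r) - gammaln(r) - gammaln(kf + 1.0) + r * np.log1p(-p) + kf * np.log(p)


def total_log_likelihood(
    data: ExpressionMatrix,
    B: MarkerMatrix | np.ndarray,
    H: np.ndarray,
    N: np.ndarray,
    lambda0: float,
    Lambda: np.ndarray,
    p: np.ndarray,
) -> float:
    """Full-data log-likelihood sum_{g,s} log NB(C_gs | r(mu_gs, N_s, p_g), p_g)."""
    Bm = B.B if isinstance(B, MarkerMatrix) else np.asarray(B)
    mu = compute_mu(H, Bm, lambda0, Lambda)
    r = nb_rate(mu, np.asarray(N, dtype=float)[None, :], np.asarray(p, dtype=float)[:, None])
    ll = nb_log_pmf(data.counts, r, np.asarray(p, dtype=float)[:, None])
    if not np.isfinite(ll).all():
        g, s = np.argwhere(~np.isfinite(ll))[0]
        raise FloatingPointError(
            f"non-finite log-likelihood contribution at gene {data.gene_ids[g]!r}, "
            f"spot {data.spot_ids[s]!r}"
        )
    return float(ll.sum())


def expected_types_per_spot(alpha: float, t_N: int) -> float:
    """Expected number of present types D = t_N * alpha / (t_N + alpha).

    Under the feature-allocation prior pi_st ~ Beta(alpha/t_N, 1),
    Z_st ~ Bernoulli(pi_st), so E[sum_t Z_st] = t_N * E[pi].
    """
    if alpha <= 0 or t_N <= 0:
        raise ValueError("alpha and t_N must be positive")
    return t_N * alpha / (t_N + alpha)


def alpha_for_expected_types(D: float, t_N: int) -> float:
    """Inverse of :func:`expected_types_per_spot`: alpha = D * t_N / (t_N - D)."""
    if not 0 < D < t_N:
        raise ValueError(f"D must lie in (0, t_N={t_N}), got {D}")
    return D * t_N / (t_N - D)
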