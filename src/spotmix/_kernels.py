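"""Compiled inner loops for the NB likelihood.

The Metropolis-within-Gibbs sweep evaluates, per iteration, on the order of
3e5 negative-binomial terms. Only the part of log NB(k | r, p) that depends
on the sampled variables is needed inside acceptance ratios:

    kernel(k, r, p) = lgamma(k + r) - lgamma(r) + r * log(1 - p)

(the -lgamma(k+1) + k*log(p) remainder is constant in r and handled by the
caller when p itself moves). For small k the lgamma difference is computed
as sum_{j<k} log(r + j), which is markedly faster than two lgamma calls.
"""

import math

import numpy as np
from numba import njit

__all__ = ["nb_kernel_colsum", "nb_kernel_rowsum", "theta_block_update"]

_SMALL_K = 1  # only k = 0 shortcuts the lgamma pair (benchmarked optimum)


@njit(cache=True, fastmath=True)
def _term(k, r, lq):
    if r <= 0.0:
        return -np.inf
    if k == 0:
        return r * lq
    if k < _SMALL_K:
        t = 0.0
        for j in range(k):
            t += math.log(r + j)
        return t + r * lq
    return math.lgamma(k + r) - math.lgamma(r) + r * lq


@njit(cache=True, fastmath=True)
def nb_kernel_colsum(C, mu, coef, lq, N):
    """Per-spot sums over genes: out[s] = sum_g kernel(C_gs, coef_g*N_s*mu_gs, lq_g).

    C : (G, S) int64 counts; mu : (G, S); coef : (G,) = (1-p)/p;
    lq : (G,) = log(1-p); N : (S,) float cell numbers.
    """
    G, S = C.shape
    out = np.zeros(S)
    for g in range(G):
        cf = coef[g]
        l = lq[g]
        for s in range(S):
            out[s] += _term(C[g, s], cf * N[s] * mu[g, s], l)
    return out


@njit(cache=True, fastmath=True)
def theta_block_update(C, M, theta, row_sums, q, coef, lq, N, prior_diff,
                       hastings, y, log_u, lambda0, cur_col, acc_out):
    """Sequential per-type Metropolis updates of the abundance matrix theta.

    Proposals ``y`` (T, S), their Hastings corrections and the Gamma prior
    log-ratios are pre-drawn by the caller (valid because column t only
    changes at its own update). ``q = (B*Lambda) @ H.T`` is the marker part
    of mu and is maintained in place together with theta, row_sums and the
    per-spot current log-likelihood ``cur_col``.

    Changing theta_st rescales the whole proportion row:
    h'_tt = theta_tt / rs_new for tt != t, so
    mu' = lambda0 + (q - M_t h_t) * rs/rs_new + M_t * y/rs_new.
    """
    G, S = C.shape
    T = theta.shape[1]
    for t in range(T):
        for s in range(S):
            x = theta[s, t]
            yy = y[t, s]
            rs = row_sums[s]
            rs_new = rs - x + yy
            ratio = rs / rs_new
            h_old = x / rs
            h_new = yy / rs_new
            ns = N[s]
            ll = 0.0
            for g in range(G):
                mt = M[g, t]
                mu_p = lambda0 + (q[g, s] - mt * h_old) * ratio + mt * h_new
                ll += _term(C[g, s], coef[g] * ns * mu_p, lq[g])
            if log_u[t, s] < ll - cur_col[s] + prior_diff[t, s] + hastings[t, s]:
                for g in range(G):
                    mt = M[g, t]
                    q[g, s] = (q[g, s] - mt * h_old) * ratio + mt * h_new
                theta[s, t] = yy
                row_sums[s] = rs_new
                cur_col[s] = ll
                acc_out[s, t] += 1.0


@njit(cache=True, fastmath=True)
def nb_kernel_rowsum(C, mu, coef, lq, N):
    """Per-gene sums over spots: out[g] = sum_s kernel(C_gs, coef_g*N_s*mu_gs, lq_g)."""
    G, S = C.shape
    out = np.zeros(G)
    for g in range(G):
        cf = coef[g]
        l = lq[g]
        acc = 0.0
        for s in range(S):
            acc += _term(C[g, s], cf * N[s] * mu[g, s], l)
        out[g] = acc
    return out
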