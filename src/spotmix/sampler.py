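"""Metropolis-within-Gibbs inference for the spot-mixture model.

Update order within one sweep (fixed, each update immediately visible to the
next): pi (exact Gibbs), Z (exact Gibbs; the dummy column is pinned at zero
under shrinkage), theta (MH, one type at a time, vectorized over spots),
N (MH with a ceiling-truncated-normal proposal), lambda0 (single global MH),
Lambda (MH per marker entry, vectorized over genes within a type), p (MH per
gene). Spot-level variables are conditionally independent across spots given
the gene-level ones and vice versa, so vectorizing over the independent axis
is mathematically identical to a sequential scan.

Continuous positive variables use a truncated-normal proposal TN(x, sigma)
on (0, inf) whose Hastings ratio is Phi(x/sigma)/Phi(y/sigma); the integer
N_s uses the ceiling of a truncated normal (support {1, 2, ...}). Flat
improper priors are placed on lambda0 and Lambda over (0, inf) and a flat
prior on p_g over (0, 1): their targets consist of likelihood terms only.

Step sizes for theta, Lambda, lambda0 and p adapt during burn-in toward a
23% acceptance rate; the N step size stays fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, log_ndtr, ndtr, ndtri

from ._kernels import nb_kernel_colsum, nb_kernel_rowsum, theta_block_update
from .data import ExpressionMatrix, Hyperparameters, MarkerMatrix
from .nb import compute_mu, compute_proportions, nb_log_pmf, nb_rate

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "ModelState",
    "ChainResult",
    "PosteriorEstimate",
    "sample_pi",
    "sample_Z",
    "sample_truncnorm",
    "sample_ceiling_truncnorm",
    "tn_hastings_log_ratio",
    "ceiltn_log_pmf",
    "ceiltn_hastings_log_ratio",
    "mh_step",
    "log_target_theta",
    "log_target_N",
    "log_target_lambda0",
    "log_target_Lambda",
    "log_target_p",
    "adapt_step_sizes",
    "initialize_state",
    "sweep",
    "run_chain",
    "run",
]


# --------------------------------------------------------------------------
# configuration and state containers

@dataclass
class SamplerConfig:
    """Run settings for the Metropolis-within-Gibbs sampler.

    Defaults follow the recommended settings for a full-size run: at least
    50,000 iterations with a 40,000-iteration burn-in, thinning 10, step
    sizes theta 0.1 / N 2.01 / lambda0 0.05 / p 0.1 with the Lambda step
    sizes set from the data (half the initial Lambda values), adaptation
    every 10,000 iterations during burn-in toward 23% acceptance.
    """

    n_iterations: int = 50_000
    burn_in: int = 40_000
    thinning: int = 10
    n_chains: int = 3
    seed: int | None = None
    step_sizes: dict = field(default_factory=lambda: {
        "theta": 0.1, "N": 2.01, "lambda0": 0.05, "p": 0.1, "Lambda": None,
    })
    adapt_interval: int = 10_000
    adapt_epsilon: float = 0.1
    target_acceptance: float = 0.23
    dummy_shrinkage: bool = True
    fix_N: bool = False
    fix_Lambda: bool = False
    literal_z_conditional: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not 0 < self.adapt_epsilon < 1:
            raise ValueError("adapt_epsilon must lie in (0, 1)")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class ModelState:
    """One configuration of all latent variables."""

    theta: np.ndarray        # (S, T) positive
    Z: np.ndarray            # (S, T) binary
    pi: np.ndarray           # (S, T) in (0, 1)
    N: np.ndarray            # (S,) integer >= 1
    lambda0: float
    Lambda: np.ndarray       # (G, T), zero where B == 0
    p: np.ndarray            # (G,) in (0, 1)

    @property
    def H(self) -> np.ndarray:
        return compute_proportions(self.theta)

    def mu(self, B: np.ndarray) -> np.ndarray:
        return compute_mu(self.H, B, self.lambda0, self.Lambda)

    def validate(self, B: MarkerMatrix, shrinkage: bool = True) -> None:
        assert (self.theta > 0).all()
        assert ((self.pi > 0) & (self.pi < 1)).all()
        assert np.isin(self.Z, (0, 1)).all()
        if shrinkage:
            assert not self.Z[:, B.dummy_index].any()
        assert (self.N >= 1).all()
        assert self.lambda0 > 0
        assert (self.Lambda[B.B == 0] == 0).all()
        assert ((self.p > 0) & (self.p < 1)).all()
        assert np.allclose(self.H.sum(axis=1), 1.0, atol=1e-9)


@dataclass
class ChainResult:
    """Retained draws and bookkeeping for one chain."""

    H_draws: np.ndarray          # (D, S, T)
    lambda0_draws: np.ndarray    # (D,)
    p_draws: np.ndarray          # (D, G)
    N_draws: np.ndarray          # (D, S)
    Lambda_draws: np.ndarray     # (D, G, T)
    loglik_draws: np.ndarray     # (D,)
    acceptance_rates: dict
    step_sizes: dict
    seed: int

    @property
    def n_draws(self) -> int:
        return self.H_draws.shape[0]

    @property
    def H_mean(self) -> np.ndarray:
        return self.H_draws.mean(axis=0)


@dataclass
class PosteriorEstimate:
    """Cross-chain posterior summary; H_mean averages retained draws, then chains."""

    H_mean: np.ndarray
    chains: list

    @property
    def chain_H_means(self) -> np.ndarray:
        return np.stack([c.H_mean for c in self.chains])


# --------------------------------------------------------------------------
# exact Gibbs conditionals

def sample_pi(Z, alpha: float, t_N: int, rng: np.random.Generator):
    """Draw pi | Z from Beta(alpha/t_N + Z, 2 - Z) elementwise."""
    Z = np.asarray(Z)
    if not np.isin(Z, (0, 1)).all():
        raise ValueError("Z must be binary")
    return rng.beta(alpha / t_N + Z, 2.0 - Z)


def _gamma_logpdf(x, a, b, normalized=True):
    x = np.asarray(x, dtype=float)
    out = (a - 1.0) * np.log(x) - b * x
    if normalized:
        out = out + a * np.log(b) - gammaln(a)
    return out


def z_posterior_prob(theta, pi, hyper: Hyperparameters, literal: bool = False):
    """P(Z=1 | theta, pi) with fully normalized Gamma densities.

    ``literal=True`` reproduces the conditional with the Gamma normalizing
    constants dropped (a non-equivalent weighting, kept for comparison).
    """
    theta = np.asarray(theta, dtype=float)
    if (theta <= 0).any():
        raise ValueError("theta must be strictly positive")
    pi = np.asarray(pi, dtype=float)
    with np.errstate(divide="ignore"):
        log_odds = (
            np.log(pi) - np.log1p(-pi)
            + _gamma_logpdf(theta, hyper.a, hyper.b, normalized=not literal)
            - _gamma_logpdf(theta, hyper.a0, hyper.b0, normalized=not literal)
        )
    return expit(log_odds)


def sample_Z(theta, pi, hyper: Hyperparameters, rng: np.random.Generator,
             literal: bool = False):
    """Exact Gibbs draw of the presence indicators Z | theta, pi."""
    prob1 = z_posterior_prob(theta, pi, hyper, literal=literal)
    return (rng.random(np.shape(prob1)) < prob1).astype(np.int8)


# --------------------------------------------------------------------------
# truncated-normal proposal machinery

def sample_truncnorm(center, sigma, rng: np.random.Generator):
    """Exact draw from TN(center, sigma) on (0, inf) by inverse CDF."""
    center = np.asarray(center, dtype=float)
    lo = ndtr(-center / sigma)
    u = rng.uniform(lo, 1.0)
    # clip away u == 1 round-off that would map to +inf
    u = np.clip(u, None, 1.0 - 1e-16)
    return center + sigma * ndtri(u)


def sample_ceiling_truncnorm(center, sigma, rng: np.random.Generator):
    """Draw ceil(X), X ~ TN(center, sigma); support {1, 2, ...}."""
    return np.ceil(sample_truncnorm(center, sigma, rng)).astype(np.int64)


def tn_hastings_log_ratio(x, y, sigma):
    """log q(x|y)/q(y|x) = log Phi(x/sigma) - log Phi(y/sigma)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return log_ndtr(x / sigma) - log_ndtr(y / sigma)


def _log_ndtr_diff(a, b):
    """log(Phi(b) - Phi(a)) for b > a, stable in both tails."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # mirror into the left tail where log_ndtr is accurate
    use_sf = (a + b) > 0
    lo = np.where(use_sf, log_ndtr(-b), log_ndtr(a))
    hi = np.where(use_sf, log_ndtr(-a), log_ndtr(b))
    with np.errstate(invalid="ignore"):
        out = hi + np.log1p(-np.exp(np.minimum(lo - hi, 0.0)))
    return out


def ceiltn_log_pmf(x, mu, sigma):
    """log P(ceil(TN(mu, sigma)) = x); -inf for x <= 0.

    P(Y=x) = [Phi((x-mu)/sigma) - Phi((x-1-mu)/sigma)] / Phi(mu/sigma).
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    val = _log_ndtr_diff((x - 1 - mu) / sigma, (x - mu) / sigma) - log_ndtr(mu / sigma)
    return np.where(x >= 1, val, -np.inf)


def ceiltn_hastings_log_ratio(x, y, sigma):
    """log q(x|y)/q(y|x) for the ceiling-truncated-normal proposal."""
    return ceiltn_log_pmf(x, y, sigma) - ceiltn_log_pmf(y, x, sigma)


def mh_step(current, log_target, step_size, rng: np.random.Generator,
            proposal_kind: str = "continuous"):
    """One scalar Metropolis-Hastings accept/reject step.

    Returns (new_value, accepted). A proposal with log-target -inf is
    rejected automatically.
    """
    lt_cur = log_target(current)
    if not np.isfinite(lt_cur):
        raise ValueError("log_target must be finite at the current value")
    if proposal_kind == "continuous":
        y = float(sample_truncnorm(current, step_size, rng))
        hastings = float(tn_hastings_log_ratio(current, y, step_size))
    elif proposal_kind == "ceiling":
        y = int(sample_ceiling_truncnorm(float(current), step_size, rng))
        hastings = float(ceiltn_hastings_log_ratio(current, y, step_size))
    else:
        raise ValueError(f"unknown proposal_kind {proposal_kind!r}")
    lt_prop = log_target(y)
    log_acc = lt_prop - lt_cur + hastings
    if np.log(rng.random()) < log_acc:
        return y, True
    return current, False


# --------------------------------------------------------------------------
# reference log-targets (readable scipy implementations; the sweep below
# evaluates the same quantities through the compiled kernels)

def _spot_loglik(C_col, theta_row, B, lambda0, Lambda, N_s, p):
    H_row = compute_proportions(theta_row)
    mu_col = compute_mu(H_row, B, lambda0, Lambda)[:, 0]
    r = nb_rate(mu_col, N_s, p)
    return float(nb_log_pmf(C_col, r, p).sum())


def log_target_theta(theta_val, t, theta_row, C_col, B, Z_row, lambda0, Lambda,
                     N_s, p, hyper: Hyperparameters):
    """Unnormalized log conditional of one theta_st (full spot likelihood + Gamma prior)."""
    if theta_val <= 0:
        return -np.inf
    row = np.array(theta_row, dtype=float)
    row[t] = theta_val
    ll = _spot_loglik(C_col, row, B, lambda0, Lambda, N_s, p) if len(C_col) else 0.0
    if Z_row[t] == 1:
        prior = _gamma_logpdf(theta_val, hyper.a, hyper.b)
    else:
        prior = _gamma_logpdf(theta_val, hyper.a0, hyper.b0)
    return ll + float(prior)


def log_target_N(N_s, theta_row, C_col, B, lambda0, Lambda, p, l_s, sigma):
    """Unnormalized log conditional of N_s (likelihood + truncated-normal prior)."""
    if N_s < 1:
        return -np.inf
    ll = _spot_loglik(C_col, theta_row, B, lambda0, Lambda, float(N_s), p) if len(C_col) else 0.0
    prior = -0.5 * ((N_s - l_s) / sigma) ** 2 - float(log_ndtr(l_s / sigma))
    return ll + prior


def _full_loglik(C, H, B, lambda0, Lambda, N, p):
    mu = compute_mu(H, B, lambda0, Lambda)
    r = nb_rate(mu, np.asarray(N, dtype=float)[None, :], np.asarray(p)[:, None])
    return float(nb_log_pmf(C, r, np.asarray(p)[:, None]).sum())


def log_target_lambda0(lambda0, C, H, B, Lambda, N, p):
    """Log conditional of the base expression (likelihood only; flat prior)."""
    if lambda0 <= 0:
        return -np.inf
    return _full_loglik(C, H, B, lambda0, Lambda, N, p)


def log_target_Lambda(value, g, t, C_row, H, B_row, lambda0, Lambda_row, N, p_g):
    """Log conditional of one over-expression entry Lambda_gt (likelihood over spots)."""
    if value < 0:
        return -np.inf
    lam = np.array(Lambda_row, dtype=float)
    lam[t] = value
    mu_row = lambda0 + H @ (np.asarray(B_row, dtype=float) * lam)
    r = nb_rate(mu_row, np.asarray(N, dtype=float), p_g)
    return float(nb_log_pmf(C_row, r, p_g).sum())


def log_target_p(p_g, g, C_row, H, B_row, lambda0, Lambda_row, N):
    """Log conditional of the NB success parameter p_g; zero density outside (0, 1)."""
    if not 0 < p_g < 1:
        return -np.inf
    mu_row = lambda0 + H @ (np.asarray(B_row, dtype=float) * np.asarray(Lambda_row, dtype=float))
    r = nb_rate(mu_row, np.asarray(N, dtype=float), p_g)
    return float(nb_log_pmf(C_row, r, p_g).sum())


def adapt_step_sizes(steps, accepted, attempts, epsilon: float, target: float = 0.23):
    """Multiplicative step-size adaptation toward the target acceptance rate.

    Per variable: sigma <- (1-eps)*sigma if the realized acceptance rate is
    below the target, else (1+eps)*sigma.
    """
    steps = np.asarray(steps, dtype=float)
    rate = np.asarray(accepted, dtype=float) / float(attempts)
    return np.where(rate < target, (1.0 - epsilon) * steps, (1.0 + epsilon) * steps)


# --------------------------------------------------------------------------
# initialization

def initialize_state(data: ExpressionMatrix, B: MarkerMatrix, hyper: Hyperparameters,
                     rng: np.random.Generator, config: SamplerConfig | None = None):
    """Starting state: Lambda from per-gene non-zero count means, theta from its
    prior, Z all-present (dummy pinned), N at the prior counts, p at 1/2,
    lambda0 at 0.2. Returns (state, lambda_step_sizes)."""
    config = config or SamplerConfig()
    G, S = data.counts.shape
    T = B.n_types
    if hyper.l is None:
        raise ValueError("Hyperparameters.l (per-spot prior cell counts) is required")
    lam_init = np.ones(G)
    for g in range(G):
        nz = data.counts[g][data.counts[g] > 0]
        if nz.size:
            lam_init[g] = nz.mean()
    Lambda = B.B.astype(float) * lam_init[:, None]
    lambda_steps = np.where(B.B == 1, lam_init[:, None] / 2.0, 0.0)
    Z = np.ones((S, T), dtype=np.int8)
    if config.dummy_shrinkage:
        Z[:, B.dummy_index] = 0
    state = ModelState(
        theta=rng.gamma(hyper.a, 1.0 / hyper.b, size=(S, T)),
        Z=Z,
        pi=rng.beta(hyper.alpha / T, 1.0, size=(S, T)),
        N=np.maximum(np.rint(hyper.l).astype(np.int64), 1),
        lambda0=0.2,
        Lambda=Lambda,
        p=np.full(G, 0.5),
    )
    return state, lambda_steps


# --------------------------------------------------------------------------
# the fast sweep engine

class _Engine:
    """Mutable chain state plus compiled-likelihood bookkeeping."""

    def __init__(self, data: ExpressionMatrix, B: MarkerMatrix,
                 hyper: Hyperparameters, config: SamplerConfig,
                 rng: np.random.Generator, state: ModelState | None = None,
                 lambda_steps: np.ndarray | None = None):
        self.data, self.B, self.hyper, self.config, self.rng = data, B, hyper, config, rng
        if state is None:
            state, lambda_steps = initialize_state(data, B, hyper, rng, config)
        self.C = np.ascontiguousarray(data.counts, dtype=np.int64)
        self.G, self.S = self.C.shape
        self.T = B.n_types
        self.Bf = B.B.astype(float)
        self.gidx = [np.flatnonzero(B.B[:, t] == 1) for t in range(self.T)]
        self.C_rowsum = self.C.sum(axis=1).astype(float)
        self._lgamma_const = -float(gammaln(self.C + 1.0).sum())

        self.theta = state.theta.astype(float).copy()
        self.Z = state.Z.astype(np.int8).copy()
        self.pi = state.pi.astype(float).copy()
        self.N = state.N.astype(np.int64).copy()
        self.lambda0 = float(state.lambda0)
        self.Lambda = state.Lambda.astype(float).copy()
        self.p = state.p.astype(float).copy()

        self.row_sums = self.theta.sum(axis=1)
        self.H = self.theta / self.row_sums[:, None]
        self.M = self.Bf * self.Lambda
        self.mu = self.lambda0 + self.M @ self.H.T
        self.coef = (1.0 - self.p) / self.p
        self.lq = np.log1p(-self.p)

        ss = dict(SamplerConfig().step_sizes)
        ss.update(config.step_sizes or {})
        self.theta_step = np.full((self.S, self.T), float(ss["theta"]))
        self.N_step = float(ss["N"])
        self.lambda0_step = float(ss["lambda0"])
        self.p_step = np.full(self.G, float(ss["p"]))
        if ss.get("Lambda") is not None:
            self.Lambda_step = np.where(B.B == 1, float(ss["Lambda"]), 0.0)
        elif lambda_steps is not None:
            self.Lambda_step = lambda_steps.astype(float).copy()
        else:
            _, self.Lambda_step = initialize_state(data, B, hyper, rng, config)

        self._reset_counters()
        self.iteration = 0

    # -- bookkeeping ----------------------------------------------------
    def _reset_counters(self):
        self.theta_acc = np.zeros((self.S, self.T))
        self.lambda0_acc = 0.0
        self.p_acc = np.zeros(self.G)
        self.Lambda_acc = np.zeros((self.G, self.T))
        self.N_acc = np.zeros(self.S)
        self.attempts = 0

    def state(self) -> ModelState:
        return ModelState(self.theta.copy(), self.Z.copy(), self.pi.copy(),
                          self.N.copy(), self.lambda0, self.Lambda.copy(), self.p.copy())

    def loglik(self, cur_col=None) -> float:
        if cur_col is None:
            cur_col = nb_kernel_colsum(self.C, self.mu, self.coef, self.lq,
                                       self.N.astype(float))
        return float(cur_col.sum()) + self._lgamma_const + float(self.C_rowsum @ np.log(self.p))

    def _refresh_derived(self):
        """Recompute incrementally-maintained arrays exactly (drift control)."""
        self.row_sums = self.theta.sum(axis=1)
        self.H = self.theta / self.row_sums[:, None]
        self.M = self.Bf * self.Lambda
        self.mu = self.lambda0 + self.M @ self.H.T

    # -- one full iteration ---------------------------------------------
    def sweep(self):
        rng, hyper, cfg = self.rng, self.hyper, self.config
        S, T, G = self.S, self.T, self.G
        Nf = self.N.astype(float)
        if self.iteration % 500 == 0 and self.iteration > 0:
            self._refresh_derived()

        # pi | Z  (exact); inlined draw, same law as sample_pi
        self.pi = rng.beta(hyper.alpha / T + self.Z, 2.0 - self.Z)

        # Z | theta, pi  (exact; dummy column pinned under shrinkage)
        prob1 = z_posterior_prob(self.theta, self.pi, hyper,
                                 literal=cfg.literal_z_conditional)
        self.Z = (rng.random((S, T)) < prob1).astype(np.int8)
        if cfg.dummy_shrinkage:
            self.Z[:, self.B.dummy_index] = 0

        # theta, one type at a time, sequential inside the compiled block.
        # Proposals/Hastings/prior ratios are pre-drawn per type: column t
        # only changes at its own update, so they are unaffected by the
        # sequential scan.
        cur_col = nb_kernel_colsum(self.C, self.mu, self.coef, self.lq, Nf)
        y = np.empty((T, S))
        hast = np.empty((T, S))
        prior = np.empty((T, S))
        for t in range(T):
            x = self.theta[:, t]
            st = self.theta_step[:, t]
            y[t] = sample_truncnorm(x, st, rng)
            hast[t] = tn_hastings_log_ratio(x, y[t], st)
            z = self.Z[:, t]
            a_eff = np.where(z == 1, hyper.a, hyper.a0)
            b_eff = np.where(z == 1, hyper.b, hyper.b0)
            prior[t] = (a_eff - 1.0) * (np.log(y[t]) - np.log(x)) - b_eff * (y[t] - x)
        log_u = np.log(rng.random((T, S)))
        q = self.mu - self.lambda0
        theta_block_update(self.C, self.M, self.theta, self.row_sums, q,
                           self.coef, self.lq, Nf, prior, hast, y, log_u,
                           self.lambda0, cur_col, self.theta_acc)
        self.H = self.theta / self.row_sums[:, None]
        self.mu = self.lambda0 + q

        # N (ceiling-TN proposal), unless counts are observed
        if not cfg.fix_N:
            x = self.N
            y = sample_ceiling_truncnorm(Nf, self.N_step, rng)
            yf = y.astype(float)
            prop_col = nb_kernel_colsum(self.C, self.mu, self.coef, self.lq, yf)
            prior_diff = -((yf - hyper.l) ** 2 - (Nf - hyper.l) ** 2) / (2.0 * hyper.sigma ** 2)
            log_acc = (prop_col - cur_col) + prior_diff \
                + ceiltn_hastings_log_ratio(x, y, self.N_step)
            acc = np.log(rng.random(S)) < log_acc
            if acc.any():
                self.N[acc] = y[acc]
                Nf = self.N.astype(float)
                cur_col[acc] = prop_col[acc]
                self.N_acc[acc] += 1

        # lambda0 (global scalar; flat prior)
        x0 = self.lambda0
        y0 = float(sample_truncnorm(x0, self.lambda0_step, rng))
        mu_prop = self.mu + (y0 - x0)
        prop_col = nb_kernel_colsum(self.C, mu_prop, self.coef, self.lq, Nf)
        log_acc = prop_col.sum() - cur_col.sum() \
            + float(tn_hastings_log_ratio(x0, y0, self.lambda0_step))
        if np.log(rng.random()) < log_acc:
            self.lambda0 = y0
            self.mu = mu_prop
            cur_col = prop_col
            self.lambda0_acc += 1

        # Lambda, per type, vectorized over that type's marker genes. The
        # per-gene current sums are computed once and maintained through
        # acceptances, then reused by the p update that follows.
        cur_row = nb_kernel_rowsum(self.C, self.mu, self.coef, self.lq, Nf)
        if not cfg.fix_Lambda:
            for t in range(T):
                gi = self.gidx[t]
                if gi.size == 0:
                    continue
                x = self.Lambda[gi, t]
                st = self.Lambda_step[gi, t]
                y = sample_truncnorm(x, st, rng)
                Csub = self.C[gi]
                musub = self.mu[gi]
                csub, lsub = self.coef[gi], self.lq[gi]
                mu_prop_sub = musub + (y - x)[:, None] * self.H[:, t][None, :]
                prop_row = nb_kernel_rowsum(Csub, mu_prop_sub, csub, lsub, Nf)
                log_acc = (prop_row - cur_row[gi]) + tn_hastings_log_ratio(x, y, st)
                acc = np.log(rng.random(gi.size)) < log_acc
                if acc.any():
                    ga = gi[acc]
                    self.Lambda[ga, t] = y[acc]
                    self.M[ga, t] = y[acc]
                    self.mu[ga] = mu_prop_sub[acc]
                    cur_row[ga] = prop_row[acc]
                    self.Lambda_acc[ga, t] += 1

        # p, per gene, vectorized; proposals >= 1 are rejected outright
        x = self.p
        y = sample_truncnorm(x, self.p_step, rng)
        valid = y < 1.0
        ysafe = np.where(valid, y, 0.5)
        coef_new = (1.0 - ysafe) / ysafe
        lq_new = np.log1p(-ysafe)
        prop_row = nb_kernel_rowsum(self.C, self.mu, coef_new, lq_new, Nf)
        log_acc = (prop_row - cur_row) \
            + self.C_rowsum * (np.log(ysafe) - np.log(x)) \
            + tn_hastings_log_ratio(x, y, self.p_step)
        acc = valid & (np.log(rng.random(G)) < log_acc)
        if acc.any():
            self.p[acc] = y[acc]
            self.coef[acc] = coef_new[acc]
            self.lq[acc] = lq_new[acc]
            self.p_acc[acc] += 1

        self.attempts += 1
        self.iteration += 1
        self._last_col = cur_col

    # -- adaptation ------------------------------------------------------
    def adapt(self):
        """Adapt step sizes from the acceptance counters; burn-in only (the
        caller enforces the schedule). Counters are reset."""
        cfg = self.config
        n = self.attempts
        if n == 0:
            return
        eps, tgt = cfg.adapt_epsilon, cfg.target_acceptance
        self.theta_step = adapt_step_sizes(self.theta_step, self.theta_acc, n, eps, tgt)
        self.lambda0_step = float(adapt_step_sizes(self.lambda0_step, self.lambda0_acc, n, eps, tgt))
        self.p_step = adapt_step_sizes(self.p_step, self.p_acc, n, eps, tgt)
        if not cfg.fix_Lambda:
            new = adapt_step_sizes(self.Lambda_step, self.Lambda_acc, n, eps, tgt)
            self.Lambda_step = np.where(self.B.B == 1, new, 0.0)
        self._reset_counters()


def sweep(state: ModelState, data: ExpressionMatrix, B: MarkerMatrix,
          hyper: Hyperparameters, config: SamplerConfig, rng: np.random.Generator,
          lambda_steps: np.ndarray | None = None):
    """Run one full sweep on ``state``; returns (new_state, acceptance dict)."""
    eng = _Engine(data, B, hyper, config, rng, state=state, lambda_steps=lambda_steps)
    eng.sweep()
    acc = {
        "theta": eng.theta_acc, "N": eng.N_acc, "lambda0": eng.lambda0_acc,
        "Lambda": eng.Lambda_acc, "p": eng.p_acc,
    }
    return eng.state(), acc


# --------------------------------------------------------------------------
# chain orchestration

def run_chain(data: ExpressionMatrix, B: MarkerMatrix, hyper: Hyperparameters,
              config: SamplerConfig, seed: int,
              init_state: ModelState | None = None) -> ChainResult:
    """Run one chain; returns thinned post-burn-in draws."""
    rng = np.random.default_rng(seed)
    eng = _Engine(data, B, hyper, config, rng, state=init_state)
    D = config.n_retained
    S, T, G = eng.S, eng.T, eng.G
    out = ChainResult(
        H_draws=np.empty((D, S, T)), lambda0_draws=np.empty(D),
        p_draws=np.empty((D, G)), N_draws=np.empty((D, S), dtype=np.int64),
        Lambda_draws=np.empty((D, G, T)), loglik_draws=np.empty(D),
        acceptance_rates={}, step_sizes={}, seed=seed,
    )
    d = 0
    total_acc = {"theta": 0.0, "N": 0.0, "lambda0": 0.0, "Lambda": 0.0, "p": 0.0}
    total_att = 0
    n_markers = int(eng.Bf.sum())
    for i in range(config.n_iterations):
        eng.sweep()
        if not np.isfinite(eng._last_col).all():
            raise FloatingPointError(f"non-finite log-likelihood at iteration {i}")
        end_of_window = eng.attempts == config.adapt_interval
        if i >= config.burn_in and (i - config.burn_in) % config.thinning == config.thinning - 1:
            if d < D:
                out.H_draws[d] = eng.H
                out.lambda0_draws[d] = eng.lambda0
                out.p_draws[d] = eng.p
                out.N_draws[d] = eng.N
                out.Lambda_draws[d] = eng.Lambda
                out.loglik_draws[d] = eng.loglik()
                d += 1
        if end_of_window:
            n = eng.attempts
            total_att += n
            total_acc["theta"] += eng.theta_acc.mean()
            total_acc["N"] += eng.N_acc.mean()
            total_acc["lambda0"] += eng.lambda0_acc
            total_acc["Lambda"] += eng.Lambda_acc.sum() / max(n_markers, 1)
            total_acc["p"] += eng.p_acc.mean()
            if i < config.burn_in:
                eng.adapt()
            else:
                eng._reset_counters()
    if eng.attempts:
        n_rem = eng.attempts
        total_att += n_rem
        total_acc["theta"] += eng.theta_acc.mean()
        total_acc["N"] += eng.N_acc.mean()
        total_acc["lambda0"] += eng.lambda0_acc
        total_acc["Lambda"] += eng.Lambda_acc.sum() / max(n_markers, 1)
        total_acc["p"] += eng.p_acc.mean()
    out.acceptance_rates = {k: v / max(total_att, 1) for k, v in total_acc.items()}
    out.step_sizes = {
        "theta": eng.theta_step, "N": eng.N_step, "lambda0": eng.lambda0_step,
        "Lambda": eng.Lambda_step, "p": eng.p_step,
    }
    assert d == D
    return out


def run(data: ExpressionMatrix, B: MarkerMatrix, hyper: Hyperparameters,
        config: SamplerConfig) -> PosteriorEstimate:
    """Run ``config.n_chains`` independent chains and average their posterior
    mean proportions."""
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_chains)]
    chains = []
    for ci, cs in enumerate(chain_seeds):
        logger.info("running chain %d/%d (seed %d)", ci + 1, config.n_chains, cs)
        chains.append(run_chain(data, B, hyper, config, cs))
    H_mean = np.mean([c.H_mean for c in chains], axis=0)
    return PosteriorEstimate(H_mean=H_mean, chains=chains)
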