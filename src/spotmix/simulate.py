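"""Ground-truthed synthetic spatial-transcriptomics data.

Datasets are drawn from the generative model itself: per-spot presence
indicators from the Beta-Bernoulli feature allocation, abundances from the
Gamma mixture, proportions by normalization, and counts from the negative
binomial with per-gene dispersion. Defaults reproduce the reference study
conditions: 800 spots, 7 types (one dummy), 149 marker genes split
15/31/35/23/17/33/0, lambda0 = 0.2, (a, b, a0, b0) = (10, 1, 0.1, 1),
alpha = 2 t_N for the dense and 0.45 t_N for the sparse mixing regime, and
on average 15 cells per spot.

The true per-gene over-expression values are resampled from a positive
pool: by default log-normal with mean-log 1 and sd-log 1, or a
user-supplied empirical vector (e.g. cell-type average expressions from a
single-cell reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import DUMMY_TYPE_NAME, ExpressionMatrix, MarkerMatrix
from .nb import compute_proportions, nb_rate

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "SCENARIOS",
    "simulate_marker_matrix",
    "simulate_truth",
    "simulate_counts",
    "apply_count_noise",
    "simulate_dataset",
    "generate_replicates",
]

DEFAULT_MARKER_COUNTS = (15, 31, 35, 23, 17, 33, 0)

#: overlap regimes: (type_a, type_b, n_shared) with 1-based non-dummy type
#: numbers; the shared genes are drawn from type_b's block and additionally
#: marked for type_a, keeping the total gene count fixed.
_OVERLAP_PAIRS = {
    "exclusive": (),
    "slight": ((2, 3, 9), (3, 4, 10)),
    "high": ((2, 3, 9), (3, 4, 10), (4, 5, 17)),
}


@dataclass
class ScenarioConfig:
    """Study conditions for one simulation scenario."""

    s_M: int = 800
    t_N: int = 7
    marker_counts: tuple = DEFAULT_MARKER_COUNTS
    density: str = "dense"             # dense: alpha = 2 t_N; sparse: 0.45 t_N
    lambda0: float = 0.2
    a: float = 10.0
    b: float = 1.0
    a0: float = 0.1
    b0: float = 1.0
    count_regime: str = "known"        # known | noisy_moderate | noisy_high | unknown
    overlap: str = "exclusive"         # exclusive | slight | high
    mean_cells: float = 15.0
    lambda_pool: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.marker_counts) != self.t_N:
            raise ValueError("marker_counts length must equal t_N")
        if self.marker_counts[-1] != 0:
            raise ValueError("the last (dummy) marker count must be 0")
        if self.density not in ("dense", "sparse"):
            raise ValueError(f"unknown density {self.density!r}")
        if self.overlap not in _OVERLAP_PAIRS:
            raise ValueError(f"unknown overlap regime {self.overlap!r}")
        if self.count_regime not in ("known", "noisy_moderate", "noisy_high", "unknown"):
            raise ValueError(f"unknown count regime {self.count_regime!r}")

    @property
    def alpha(self) -> float:
        return 2.0 * self.t_N if self.density == "dense" else 0.45 * self.t_N

    @property
    def n_genes(self) -> int:
        return int(sum(self.marker_counts))


#: named scenario shortcuts for the CLI
SCENARIOS = {
    f"{d}-{r}": {"density": d, "count_regime": r}
    for d in ("dense", "sparse")
    for r in ("known", "noisy-moderate", "noisy-high", "unknown")
} | {
    f"{d}-{o}-overlap": {"density": d, "overlap": o}
    for d in ("dense", "sparse")
    for o in ("slight", "high")
}


@dataclass
class SimulatedDataset:
    """One replicate: observed data plus the generating truth."""

    data: ExpressionMatrix
    B: MarkerMatrix
    truth: dict = field(repr=False)
    observed_counts: np.ndarray | None
    config: ScenarioConfig
    seed: int | None = None

    @property
    def H_true(self) -> np.ndarray:
        return self.truth["H"]


def simulate_marker_matrix(config: ScenarioConfig, rng: np.random.Generator) -> MarkerMatrix:
    """Block marker signature with the configured overlap regime.

    The total gene count stays fixed across regimes; shared genes (rows with
    sum 2) are chosen seed-driven inside the blocks named by the regime.
    """
    counts = list(config.marker_counts)
    T = config.t_N
    G = config.n_genes
    B = np.zeros((G, T), dtype=np.int8)
    starts = np.concatenate([[0], np.cumsum(counts)])
    for t in range(T):
        B[starts[t]:starts[t + 1], t] = 1
    shared_rows: set[int] = set()
    for ta, tb, n_shared in _OVERLAP_PAIRS[config.overlap]:
        block = [g for g in range(starts[tb - 1], starts[tb]) if g not in shared_rows]
        if n_shared > len(block):
            raise ValueError(f"cannot share {n_shared} genes from a block of {len(block)}")
        chosen = rng.choice(block, size=n_shared, replace=False)
        B[chosen, ta - 1] = 1
        shared_rows.update(int(g) for g in chosen)
    gene_ids = [f"gene_{g + 1:04d}" for g in range(G)]
    type_names = [f"type_{t + 1}" for t in range(T - 1)] + [DUMMY_TYPE_NAME]
    return MarkerMatrix(B, gene_ids, type_names, dummy_index=T - 1)


def simulate_truth(config: ScenarioConfig, B: MarkerMatrix, rng: np.random.Generator) -> dict:
    """Draw all latent variables from their priors."""
    S, T, G = config.s_M, config.t_N, config.n_genes
    pi = rng.beta(config.alpha / T, 1.0, size=(S, T))
    Z = (rng.random((S, T)) < pi).astype(np.int8)
    shape = np.where(Z == 1, config.a, config.a0)
    rate = np.where(Z == 1, config.b, config.b0)
    theta = rng.gamma(shape, 1.0 / rate)
    H = compute_proportions(theta)
    N = np.maximum(rng.poisson(config.mean_cells, size=S), 1).astype(np.int64)
    eps = 1e-6
    p = rng.uniform(eps, 1.0 - eps, size=G)
    if config.lambda_pool is not None:
        pool = np.asarray(config.lambda_pool, dtype=float)
        if (pool <= 0).any():
            raise ValueError("lambda_pool must be strictly positive")
        draws = rng.choice(pool, size=(G, T))
    else:
        draws = rng.lognormal(mean=1.0, sigma=1.0, size=(G, T))
    Lambda = np.where(B.B == 1, draws, 0.0)
    return {"pi": pi, "Z": Z, "theta": theta, "H": H, "N": N, "p": p,
            "Lambda": Lambda, "lambda0": config.lambda0}


def simulate_counts(truth: dict, B: MarkerMatrix, rng: np.random.Generator) -> ExpressionMatrix:
    """Sample C_gs ~ NB(N_s (1-p_g)/p_g mu_gs, p_g) independently.

    numpy's negative_binomial(n, p) success probability equals 1 - p of this
    model's convention.
    """
    H, N, p = truth["H"], truth["N"], truth["p"]
    mu = truth["lambda0"] + (B.B * truth["Lambda"]) @ H.T
    r = nb_rate(mu, N[None, :].astype(float), p[:, None])
    counts = rng.negative_binomial(r, 1.0 - p[:, None])
    spot_ids = [f"spot_{s + 1:04d}" for s in range(H.shape[0])]
    return ExpressionMatrix(counts.astype(np.int64), list(B.gene_ids), spot_ids)


_NOISE = {"noisy_moderate": (2.0, 3.0), "noisy_high": (5.0, 5.0)}


def apply_count_noise(N: np.ndarray, regime: str, rng: np.random.Generator):
    """Per-spot observed cell counts l under the given noise regime.

    noisy regimes: draw e ~ N(mean, sd), flip its sign with probability 1/2
    and set l = max(1, round(N + e)). 'known' returns N itself; 'unknown'
    returns None (no usable prior counts).
    """
    N = np.asarray(N)
    if regime == "known":
        return N.astype(np.int64).copy()
    if regime == "unknown":
        return None
    if regime not in _NOISE:
        raise ValueError(f"unknown count regime {regime!r}")
    mean, sd = _NOISE[regime]
    e = rng.normal(mean, sd, size=N.shape)
    sign = rng.choice([-1.0, 1.0], size=N.shape)
    return np.maximum(np.rint(N + sign * e), 1).astype(np.int64)


def simulate_dataset(config: ScenarioConfig, seed: int | None = None) -> SimulatedDataset:
    """One full replicate under ``config`` (seed overrides config.seed)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    B = simulate_marker_matrix(config, rng)
    truth = simulate_truth(config, B, rng)
    data = simulate_counts(truth, B, rng)
    observed = apply_count_noise(truth["N"], config.count_regime, rng)
    return SimulatedDataset(data=data, B=B, truth=truth, observed_counts=observed,
                            config=config, seed=seed)


def generate_replicates(config: ScenarioConfig, n_replicates: int):
    """Independent replicates with seeds spawned from ``config.seed``.

    Returns (datasets, manifest); the manifest records per-replicate seeds
    so any replicate can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    datasets = [simulate_dataset(replace(config, seed=sd)) for sd in seeds]
    manifest = {
        "master_seed": config.seed,
        "n_replicates": n_replicates,
        "replicate_seeds": seeds,
        "scenario": {
            "s_M": config.s_M, "t_N": config.t_N, "density": config.density,
            "count_regime": config.count_regime, "overlap": config.overlap,
            "marker_counts": list(config.marker_counts),
            "lambda0": config.lambda0, "mean_cells": config.mean_cells,
        },
    }
    return datasets, manifest
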