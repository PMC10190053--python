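"""Model/Results interface for spot deconvolution.

``SpotMixtureModel`` bundles the observed counts, the binary marker
signature and the per-spot prior cell counts; ``fit`` runs the
Metropolis-within-Gibbs sampler and returns a ``SpotMixtureResults`` with
posterior mean proportions, acceptance diagnostics and convergence checks.

Example
-------
>>> from spotmix import simulate, SpotMixtureModel
>>> ds = simulate.simulate_dataset(simulate.ScenarioConfig(s_M=60, seed=7))
>>> model = SpotMixtureModel(ds.data, ds.B, cell_counts=ds.observed_counts,
...                          alpha=14.0)
>>> res = model.fit(n_iterations=2000, burn_in=1000, seed=1, n_chains=1)
>>> res.proportions.shape
(60, 7)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, Hyperparameters, MarkerMatrix
from .metrics import gelman_rubin
from .sampler import PosteriorEstimate, SamplerConfig, run

__all__ = ["SpotMixtureModel", "SpotMixtureResults"]


class SpotMixtureModel:
    """Marker-gene-driven NB mixture model for spot-level cell-type composition.

    Parameters
    ----------
    counts
        ``ExpressionMatrix`` or gene x spot DataFrame of read counts
        (marker genes only).
    markers
        ``MarkerMatrix`` or gene x type 0/1 DataFrame (a dummy column is
        appended when absent).
    cell_counts
        Per-spot prior cell numbers l_s (image-derived). Optional: when
        omitted, the model runs in unknown-counts mode with an
        uninformative prior (l_s constant, large sigma).
    alpha, a, b, a0, b0, sigma
        Hyperparameters; see :class:`spotmix.data.Hyperparameters`.
    """

    UNKNOWN_COUNTS_L = 10.0
    UNKNOWN_COUNTS_SIGMA = 1e3

    def __init__(self, counts, markers, cell_counts=None, *, alpha: float = 10.0,
                 a: float = 10.0, b: float = 1.0, a0: float = 0.1, b0: float = 1.0,
                 sigma: float = 4.0):
        if isinstance(counts, pd.DataFrame):
            counts = ExpressionMatrix.from_frame(counts)
        if isinstance(markers, pd.DataFrame):
            markers = MarkerMatrix.from_frame(markers)
        genes = [g for g in markers.gene_ids if g in set(counts.gene_ids)]
        if len(genes) < markers.n_genes:
            missing = sorted(set(markers.gene_ids) - set(genes))
            raise ValueError(f"marker genes absent from the count matrix: {missing[:5]}")
        if list(counts.gene_ids) != list(markers.gene_ids):
            counts = counts.subset_genes(list(markers.gene_ids))
        self.data = counts
        self.markers = markers
        self.unknown_counts = cell_counts is None
        if self.unknown_counts:
            l = np.full(counts.n_spots, self.UNKNOWN_COUNTS_L)
            sigma = self.UNKNOWN_COUNTS_SIGMA
        else:
            if isinstance(cell_counts, pd.Series):
                cell_counts = cell_counts.reindex(counts.spot_ids)
                if cell_counts.isna().any():
                    bad = list(cell_counts.index[cell_counts.isna()])[:5]
                    raise ValueError(f"cell counts missing for spots: {bad}")
            l = np.asarray(cell_counts, dtype=float)
            if l.shape != (counts.n_spots,):
                raise ValueError("cell_counts length must equal the number of spots")
        self.hyper = Hyperparameters(alpha=alpha, a=a, b=b, a0=a0, b0=b0, l=l, sigma=sigma)

    @classmethod
    def from_files(cls, counts_path, markers_path, cell_counts_path=None, **kwargs):
        from . import io
        counts = io.read_counts(counts_path)
        markers = io.read_marker_matrix(markers_path, counts)
        cell_counts = None
        if cell_counts_path is not None:
            cell_counts = io.read_cell_counts(cell_counts_path, counts.spot_ids)
        return cls(counts, markers, cell_counts=cell_counts, **kwargs)

    def fit(self, *, n_iterations: int = 50_000, burn_in: int = 40_000,
            thinning: int = 10, n_chains: int = 3, seed: int | None = None,
            fix_N: bool = False, Lambda_fixed: np.ndarray | None = None,
            step_sizes: dict | None = None, adapt_interval: int = 10_000,
            adapt_epsilon: float = 0.1, dummy_shrinkage: bool = True,
            ) -> "SpotMixtureResults":
        """Sample the posterior and return results.

        ``fix_N=True`` treats the supplied cell counts as observed (the
        "known counts" mode). ``Lambda_fixed`` clamps the over-expression
        matrix to the given gene x type values instead of inferring it.
        """
        config = SamplerConfig(
            n_iterations=n_iterations, burn_in=burn_in, thinning=thinning,
            n_chains=n_chains, seed=seed,
            step_sizes=step_sizes or SamplerConfig().step_sizes,
            adapt_interval=adapt_interval, adapt_epsilon=adapt_epsilon,
            dummy_shrinkage=dummy_shrinkage,
            fix_N=fix_N, fix_Lambda=Lambda_fixed is not None,
        )
        if fix_N and self.unknown_counts:
            raise ValueError("fix_N requires cell counts")
        hyper = self.hyper
        data, markers = self.data, self.markers
        if Lambda_fixed is not None:
            Lambda_fixed = np.asarray(Lambda_fixed, dtype=float)
            if Lambda_fixed.shape != markers.B.shape:
                raise ValueError("Lambda_fixed must be gene x type, matching the marker matrix")
            estimate = _run_with_fixed_lambda(data, markers, hyper, config, Lambda_fixed)
        else:
            estimate = run(data, markers, hyper, config)
        return SpotMixtureResults(self, estimate, config)


def _run_with_fixed_lambda(data, markers, hyper, config, Lambda_fixed):
    from .sampler import ChainResult, initialize_state, run_chain

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_chains)]
    chains: list[ChainResult] = []
    for cs in seeds:
        rng = np.random.default_rng(cs)
        state, _ = initialize_state(data, markers, hyper, rng, config)
        state.Lambda = markers.B.astype(float) * Lambda_fixed
        chains.append(run_chain(data, markers, hyper, config, cs, init_state=state))
    H_mean = np.mean([c.H_mean for c in chains], axis=0)
    return PosteriorEstimate(H_mean=H_mean, chains=chains)


class SpotMixtureResults:
    """Posterior summary of a fitted spot-mixture model."""

    def __init__(self, model: SpotMixtureModel, estimate: PosteriorEstimate,
                 config: SamplerConfig):
        self.model = model
        self.estimate = estimate
        self.config = config

    # -- primary quantities ---------------------------------------------
    @property
    def proportions(self) -> pd.DataFrame:
        """Posterior mean cell-type proportions, spots x types (rows sum to 1)."""
        return pd.DataFrame(self.estimate.H_mean, index=self.model.data.spot_ids,
                            columns=self.model.markers.type_names)

    @property
    def H_mean(self) -> np.ndarray:
        return self.estimate.H_mean

    @property
    def chains(self):
        return self.estimate.chains

    @property
    def lambda0_mean(self) -> float:
        return float(np.mean([c.lambda0_draws.mean() for c in self.chains]))

    @property
    def p_mean(self) -> np.ndarray:
        return np.mean([c.p_draws.mean(axis=0) for c in self.chains], axis=0)

    @property
    def N_mean(self) -> np.ndarray:
        return np.mean([c.N_draws.mean(axis=0) for c in self.chains], axis=0)

    @property
    def Lambda_mean(self) -> np.ndarray:
        return np.mean([c.Lambda_draws.mean(axis=0) for c in self.chains], axis=0)

    def dominant_types(self) -> pd.Series:
        """Per-spot type with the highest posterior mean proportion."""
        H = self.proportions
        return H.idxmax(axis=1)

    # -- diagnostics -----------------------------------------------------
    def acceptance_rates(self) -> pd.DataFrame:
        return pd.DataFrame([c.acceptance_rates for c in self.chains])

    def gelman_rubin(self, variable: str = "lambda0") -> float:
        """Potential scale reduction across chains for a scalar trace
        ('lambda0' or 'loglik'); needs >= 2 chains."""
        traces = [getattr(c, f"{variable}_draws") for c in self.chains]
        return gelman_rubin(np.stack(traces))

    def summary(self) -> str:
        lines = [
            "Spot-mixture deconvolution results",
            "==================================",
            f"spots: {self.model.data.n_spots}   marker genes: {self.model.data.n_genes}   "
            f"types: {self.model.markers.n_types} (incl. dummy)",
            f"chains: {self.config.n_chains}   iterations: {self.config.n_iterations}   "
            f"burn-in: {self.config.burn_in}   thinning: {self.config.thinning}   "
            f"retained draws/chain: {self.config.n_retained}",
            f"posterior mean lambda0: {self.lambda0_mean:.4f}",
            "",
            "mean proportions by type:",
        ]
        mean_by_type = self.proportions.mean(axis=0)
        for name, v in mean_by_type.items():
            lines.append(f"  {name:<16s} {v:8.4f}")
        acc = self.acceptance_rates().mean(axis=0)
        lines.append("")
        lines.append("mean acceptance rates: "
                     + "  ".join(f"{k}={v:.2f}" for k, v in acc.items()))
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_proportions(self, coords: pd.DataFrame, types=None, ax=None, **scatter_kw):
        """Scatter spots at their array coordinates colored by the proportion
        of each requested type (one panel per type)."""
        import matplotlib.pyplot as plt

        H = self.proportions
        types = list(types) if types is not None else list(H.columns)
        coords = coords.loc[H.index]
        if ax is None:
            fig, axes = plt.subplots(1, len(types), figsize=(4 * len(types), 3.6),
                                     squeeze=False)
            axes = axes[0]
        else:
            axes = np.atleast_1d(ax)
        for a, t in zip(axes, types):
            sc = a.scatter(coords.iloc[:, 0], coords.iloc[:, 1], c=H[t],
                           s=scatter_kw.pop("s", 14), cmap=scatter_kw.pop("cmap", "magma"),
                           **scatter_kw)
            a.set_title(str(t))
            a.set_aspect("equal")
            plt.colorbar(sc, ax=a)
        return axes
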