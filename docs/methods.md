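# Methods

## Model

A spatial-transcriptomics (ST) spot aggregates the RNA of `N_s` cells drawn
from `t_N` cell types in unknown proportions `h_s·`. The package models the
observed read count `C_gs` of marker gene `g` in spot `s` as negative
binomial,

    C_gs | mu_gs, N_s, p_g  ~  NB( N_s * (1 - p_g) / p_g * mu_gs ,  p_g ),
    mu_gs = sum_t h_st * (lambda0 + B_gt * Lambda_gt),

in the convention `P(X=k) = Gamma(k+r)/(Gamma(r) k!) (1-p)^r p^k` with mean
`r p/(1-p)`; `p_g` captures per-gene over-dispersion. The NB family is
additive in `r` at shared `p`, which is exactly what makes the per-cell
counts sum to the spot-level law above. Note scipy/numpy parameterize the
negative binomial with success probability `1 - p` of this convention.

Every cell expresses every gene at a base rate `lambda0`; a cell of type `t`
additionally expresses gene `g` at `Lambda_gt` when `B_gt = 1`, where `B` is
the observed binary marker signature. A *dummy* type with an all-zero column
in `B` absorbs cells of unrepresented types.

Composition is parameterized through unnormalized abundances: a
Beta-Bernoulli feature allocation

    pi_st ~ Beta(alpha / t_N, 1),   Z_st ~ Bernoulli(pi_st)

decides which types are present, abundances follow a two-component Gamma
mixture `theta_st | Z_st=1 ~ Gamma(a, b)` and `theta_st | Z_st=0 ~
Gamma(a0, b0)` (the second concentrated near zero), and the proportions are
`h_st = theta_st / sum_t theta_st` — equivalently, rows of `H` are Dirichlet
conditional on the `theta` row. The per-spot cell number `N_s` has a
truncated-normal prior centred at an image-derived count `l_s` with spread
`sigma`; `sigma` is treated as a standard deviation throughout (it enters
all densities and Hastings ratios as `Phi(x / sigma)`).

`alpha` controls how many types a spot holds in expectation:
`D = E[sum_t Z_st] = t_N * alpha / (t_N + alpha)`, inverted by
`alpha = D * t_N / (t_N - D)`, so users can set `alpha` from an intuition
about `D`.

## Inference

A Metropolis-within-Gibbs sampler updates, in fixed order within a sweep:
`pi` and `Z` by exact Gibbs draws from their closed-form conditionals;
`theta` (per spot-type entry), `N_s`, `lambda0`, `Lambda_gt` (marker entries
only) and `p_g` by single Metropolis-Hastings steps. New values are used
immediately. Spot-level updates are vectorized across spots (and gene-level
ones across genes), which is mathematically identical to a sequential scan
because those blocks are conditionally independent given the variables held
fixed.

The conditional for `Z` is implemented with fully normalized Gamma
densities — the two branches have different normalizing constants, which do
not cancel; a `literal_z_conditional` switch reproduces the unnormalized
weighting for comparison. Flat improper priors are used for `lambda0` and
`Lambda` on (0, inf) and a flat prior for `p_g` on (0, 1): their
conditionals consist of likelihood terms only, and `p` proposals landing at
or above 1 are rejected outright.

Positive continuous variables use a truncated-normal proposal `TN(x, step)`
on (0, inf), whose Hastings ratio is `Phi(x/step) / Phi(y/step)`. The
integer `N_s` uses the ceiling of a truncated normal, with pmf
`P(Y=x) = [Phi((x-mu)/s) - Phi((x-1-mu)/s)] / Phi(mu/s)` on {1, 2, ...};
its Hastings ratio is computed as the difference of the two log-pmfs, which
is algebraically equal to the closed form and numerically stable in the
tails (computed via log-CDF differences mirrored into the accurate tail).

Step sizes for `theta`, `Lambda`, `lambda0` and `p` adapt multiplicatively
toward a 23% acceptance rate — per scalar variable, every `adapt_interval`
iterations, only during burn-in; the `N` step stays fixed. Defaults follow
the recommended full-scale settings (iterations >= 50,000, burn-in >=
40,000, thinning 10, steps theta 0.1 / N 2.01 / lambda0 0.05 / p 0.1,
adaptation every 10,000). `Lambda` is initialized per gene at the mean of
its non-zero counts (fallback 1.0 for all-zero genes) with step sizes at
half those values; `theta` starts from its presence prior, `Z` at
all-present, `N` at `round(l_s)`, `p` at 0.5 and `lambda0` at 0.2.

Chains run independently from seeds spawned off one master seed
(reproducible bit-for-bit); posterior proportions are the retained-draw
average, then averaged across chains. The likelihood sweep evaluates ~3e5
NB terms per iteration; the inner kernels are numba-compiled with a
small-count fast path (`lgamma(k+r) - lgamma(r) = sum_{j<k} log(r+j)`),
about 4x faster than the vectorized scipy equivalent, which the test suite
uses as the reference.

### Hyperparameter defaults

| parameter | default | meaning |
|---|---|---|
| alpha | 10 | feature-allocation concentration (expected types/spot via D formula) |
| a, b | 10, 1 | Gamma(shape, rate) of theta for present types (mean 10) |
| a0, b0 | 0.1, 1 | same for absent types (mean 0.1) |
| sigma | 4 | sd of the truncated-normal prior on N_s (cells) |
| lambda0 init | 0.2 | base expression per cell (counts/gene) |

With no usable cell counts the model runs in unknown-counts mode:
`l_s = 10` for every spot with `sigma = 1e3`, i.e. an effectively flat
prior on {1, 2, ...}; the constant only anchors the initialization.

## Marker selection

Candidates per type are sieved in four steps: (1) keep genes expressed
above level `r_K` in strictly more than `r_N` spots (defaults 0 and 5);
(2) correlate each retained gene with the type's lead gene across spots —
Kendall tau-b (tie-corrected, appropriate for tie-heavy counts) and
Pearson; (3) normalize each type's tau and rho vectors by their maxima;
(4) keep genes with normalized tau > tau* AND normalized rho > rho*, where
a gene attaining the maximum (normalized value exactly 1) always passes, so
a lead gene cannot exclude itself. Genes assigned to more than 2 types are
removed entirely, and a zero dummy column is appended. Thresholds may be
global or per type.

## Synthetic data

The simulator draws every latent variable from the model's own priors:
`pi`, `Z`, `theta` (hence `H`) as above, `p_g ~ Uniform(0, 1)`, `N_s ~
Poisson(15)` truncated at 1 (the mean cell count is stated by the study
conditions, the distribution is this package's choice), and counts from the
NB law. Defaults: 800 spots, 7 types including the dummy, markers split
15/31/35/23/17/33/0 across types (154 genes; the source conditions also
quote a 149 total inconsistent with this split — the per-type split is kept
as the more specific figure), `lambda0 = 0.2`, `(a, b, a0, b0) = (10, 1,
0.1, 1)`, `alpha = 2 t_N` (dense mixing, ~4.7 types/spot) or `0.45 t_N`
(sparse, ~2.2).

True over-expression values `Lambda_gt` are resampled from a positive pool;
the default pool is log-normal (mean-log 1, sd-log 1), standing in for
cell-type average expressions that would otherwise come from a single-cell
reference; a user-supplied empirical vector is accepted. Accuracy results
depend on this choice — weaker marker effects make deconvolution harder —
so comparisons should hold the pool fixed.

Count-prior regimes: *known* passes the true `N_s` as `l_s`;
*noisy-moderate*/*noisy-high* perturb them by `+/- |e|, e ~ N(2, 3)` or
`N(5, 5)` (interpreted as mean and sd; sign flipped with probability 1/2;
rounded, floored at 1); *unknown* provides no counts. Marker-overlap
regimes keep the total gene count fixed and share 9 genes between types 2-3
plus 10 between 3-4 (*slight*), adding 17 between 4-5 (*high*); which
specific genes are shared is seed-driven.

Spots are simulated independently: the generator reproduces the model's
count law, mixing structure and noise regimes, but no spatial
autocorrelation, platform artefacts (capture efficiency gradients, segment
effects), mis-specified markers or real marker co-expression structure.
Passing the simulation tests therefore demonstrates correct inference under
the model's own assumptions, not robustness to their violation.

## Evaluation protocol and desk-scale settings

Accuracy is the average absolute error between true and estimated
proportion matrices, `sum_ij |h_ij - hhat_ij| / (t_N s_M)`, bounded by
`2/t_N` (0.29 at 7 types, attained by two different one-hot rows), plus the
fraction of spots whose estimated argmax type matches the truth (ties break
toward the lowest index, with a warning).

The bundled benchmark (`spotmix.benchmark.evaluate_scenario`, used by
`scripts/acceptance.py` and the acceptance tests) scales the original
conditions down to desk size: 150 spots, 3 replicates per scenario cell,
one chain per fit, thinning 10, adaptation every 100 burn-in iterations
with epsilon 0.25 (faster adaptation compensating for the shorter burn-in,
per the recommendation to shorten the adaptation interval for shorter
runs). Chain length is set per cell (`benchmark.CELLS`): 3,500/2,000
iterations/burn-in for the known-counts accuracy cells, 5,000/2,500 for the
sparse known-counts cell — its dominant-type statistic converges slowest,
since sparse spots hold ~2 types and close calls between them settle only
once the over-expression profiles stabilize — and 3,000/1,750 for the
robustness cells (noisy/unknown counts, marker overlap), whose error
plateaus earlier. Pilot chains at these sizes pass Gelman-Rubin (R-hat <
1.1 on the log-likelihood across seeds) and the error trajectories plateau
within the allotted lengths. Two protocol choices deserve emphasis:

* **No dummy shrinkage on simulated data.** Pinning `Z[:, dummy] = 0` is
  part of the real-data workflow (a shrinkage prior on the unknown-type
  fraction). The synthetic truth draws the dummy's presence from the same
  feature-allocation prior as every other type (mean fraction ~0.14), so
  shrinkage would floor the error metric near 0.04 regardless of fit
  quality; benchmark fits sample the dummy like any other type.
* **`sigma` tracks the stated count noise.** The prior strength should
  reflect confidence in the count estimates: 1 cell for noise-free priors,
  3 and 5 matching the moderate/high noise sd, 1e3 when counts are unknown.

## Numerical choices

* All probability computations in log space; `log Phi` via `log_ndtr`;
  `log(Phi(b) - Phi(a))` mirrored into the left tail before `log1p(-exp())`.
* Truncated-normal proposals drawn exactly by inverse CDF (no rejection
  loops), so runs are reproducible with a fixed draw count per iteration.
* Degenerate inputs fail loudly: non-positive abundances, all-zero
  proportion rows, `p` outside (0, 1), constant vectors in Moran's I, and
  non-finite likelihood contributions abort with the offending index.
* Moran's I uses a binary symmetric k-nearest-neighbour graph (k = 6,
  matching the hexagonal Visium neighbourhood; union symmetrization,
  optional distance cutoff) since the weights scheme is otherwise
  unspecified. Co-occurrence significance is two-sided at 0.05 with no
  multiplicity correction; correlations with p > 0.05 are flagged
  insignificant.
* Gelman-Rubin is the classic potential-scale-reduction factor
  `sqrt(((n-1)/n W + B/n)/W)` (no rank normalization), adequate for the
  well-behaved scalar traces it is applied to here.

## Limitations

* Dense likelihood only; at paper scale (a few hundred genes x a few
  thousand spots) this is adequate, but very large panels would want a
  sparse fast path.
* The sampler is single-site random-walk MH inside Gibbs; posterior
  exploration relies on the adaptive steps and is slow for strongly
  correlated blocks (`N_s` with `theta` row scale, `lambda0` with `p`).
* The unknown-counts mode leaves `N_s` only weakly identified (through the
  NB mean structure); reported proportions remain accurate but `N_s` itself
  should not be interpreted.
* Marker selection assumes the lead genes are correct; it cannot rescue a
  wrong lead, only filter candidates against it.
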