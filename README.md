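# spotmix

Marker-gene-driven Bayesian cell-type deconvolution for spatial
transcriptomics (ST) spots.

Each capture spot on an ST slide (e.g. 10x Visium) pools the RNA of roughly
1–100 cells of mixed types. `spotmix` estimates the fractional cell-type
composition of every spot from three inputs only — the spot × gene count
matrix restricted to marker genes, a binary marker signature per cell type,
and (optionally) per-spot cell counts estimated from the H&E image — with
**no single-cell reference dataset**. It is aimed at ST analysts who have
curated marker knowledge for the tissue at hand but no matched scRNA-seq.

## Model

Counts are negative binomial with the spot's composition inside the mean:

```
C_gs | μ_gs, N_s, p_g ~ NB( N_s · (1−p_g)/p_g · μ_gs , p_g ),
μ_gs = Σ_t h_st · (λ0 + B_gt Λ_gt)
```

where `h_s·` are the spot's type proportions, `λ0` a shared base expression
per cell, `Λ_gt` the marker over-expression (inferred, not taken from a
reference), `p_g` per-gene over-dispersion and `N_s` the number of cells in
the spot (truncated-normal prior around the image-derived count).
Composition comes from a Beta-Bernoulli feature allocation (`π_st ~
Beta(α/t_N, 1)`, `Z_st ~ Bernoulli(π_st)`) over a two-component Gamma on
unnormalized abundances `θ_st`, normalized to `h_st = θ_st / Σ_t θ_st`. A
zero-column *dummy type* absorbs cells of unlisted types. Inference is
Metropolis-within-Gibbs with exact draws for `π, Z`, truncated-normal
random-walk proposals elsewhere, and step sizes adapted toward 23%
acceptance during burn-in. See `docs/methods.md` for the full treatment.

## Worked example

Simulate a sparse-mixing dataset from the generative model (100 spots, 7
types including the dummy, 154 marker genes) and recover the composition:

```python
from spotmix import simulate, SpotMixtureModel
from spotmix.metrics import average_absolute_error, dominant_type_accuracy

cfg = simulate.ScenarioConfig(s_M=100, density="sparse", seed=7)
ds = simulate.simulate_dataset(cfg)

model = SpotMixtureModel(ds.data, ds.B, cell_counts=ds.observed_counts,
                         alpha=cfg.alpha, sigma=1.0)
res = model.fit(n_iterations=3000, burn_in=1500, thinning=10, n_chains=2,
                seed=1, adapt_interval=100, adapt_epsilon=0.25,
                dummy_shrinkage=False)
print(res.summary())
print("error vs truth:", round(average_absolute_error(ds.H_true, res.H_mean), 4))
```

prints (about a minute on one CPU):

```
Spot-mixture deconvolution results
==================================
spots: 100   marker genes: 154   types: 7 (incl. dummy)
chains: 2   iterations: 3000   burn-in: 1500   thinning: 10   retained draws/chain: 150
posterior mean lambda0: 0.2014

mean proportions by type:
  type_1             0.1388
  type_2             0.1238
  type_3             0.1139
  type_4             0.1556
  type_5             0.1511
  type_6             0.1558
  dummy              0.1611

mean acceptance rates: theta=0.43  N=0.29  lambda0=0.21  Lambda=0.21  p=0.31

error vs truth: 0.0239
```

The average absolute proportion error of 0.024 sits near the bottom of its
attainable range [0, 2/7 ≈ 0.29]; the simulated base expression was 0.2 and
the posterior mean recovers 0.201. `res.proportions` is a spots × types
DataFrame (rows sum to 1), `res.gelman_rubin("lambda0")` gives the
cross-chain R̂ (1.00 here), and `res.plot_proportions(coords)` maps any
type's fraction over the slide.

## Command line

```
spotmix select-markers --counts counts.csv --candidates cand.csv \
        --lead-genes leads.csv --out markers.csv
spotmix simulate --scenario sparse-known --replicates 3 --out sim/
spotmix fit --counts counts.csv --markers markers.csv \
        --cell-counts cells.csv --chains 3 --seed 1 --out fit/
spotmix evaluate --true-h sim/replicate_01/truth_H.csv \
        --est-h fit/proportions.csv --coords coords.csv --out eval/
spotmix diagnose --fit-dir fit/ --out diagnostics.json
```

Every run writes a manifest (config, seeds, version, config hash); reruns
with the same seed are bit-identical.

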