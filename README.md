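# diatomseason

Seasonality analysis for stream benthic-diatom monitoring.

Benthic diatoms respond within days to light, temperature, nutrients and
flow, and regulatory monitoring summarises them as an Ecological Quality
Ratio (EQR) banded into high/good/moderate/poor/bad status.  Monthly
sampling is never exactly regular, and the seasonal cycle itself drifts
from year to year — so asking "is there recurring seasonality, and how
strong is it?" needs a decomposition that handles irregular sampling and
time-varying amplitude.  `diatomseason` provides that chain for
freshwater ecologists and catchment scientists:

* **ASDHR** (Arbitrary-Sampled Dynamic Harmonic Regression): an
  unobserved-components decomposition

      y_t = T_t + S_t + e_t,   S_t = Σ_i [a_{i,t} cos(ω_i t) + b_{i,t} sin(ω_i t)]

  where the trend `T_t` and the harmonic coefficients `a_{i,t}`,
  `b_{i,t}` are stochastic time-varying parameters (integrated random
  walk and random walks), estimated by Kalman filtering and
  fixed-interval smoothing directly on the irregular sampling instants —
  process noise accumulates in proportion to each actual gap.  Noise
  variance ratios and the observation-noise variance are estimated by
  maximum likelihood; the fit reports R², an ANOVA-style F test on
  effective degrees of freedom, and 95% bands.
* **Diatom metrics**: valve-count matrices → weighted-mean-sensitivity
  index → EQR → WFD status bands (0.8/0.6/0.4/0.2, ties upward), with a
  pluggable trait table.
* **Antecedent windows**: 21-day backward means of 15-minute sensor
  series (rainfall, discharge, TRP, nitrate-N, temperature, radiation,
  DO, pH, turbidity, conductivity) aligned to each biological sample.
* **Ordination**: covariance PCA of the log-transformed species matrix
  with environmental variables projected passively as correlation
  arrows.
* **Synthetic data**: seeded generators for irregular EQR series with
  drifting seasonal amplitude, 300-valve seasonal count matrices and
  event-driven sensor series, each with a ground-truth sidecar.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Generate a synthetic dataset and run the two main stages:

```sh
diatomseason simulate all --seed 1 --out data
diatomseason fit-season --input data/eqr_series.csv --period 1.0 --harmonics 2 --out fit
```

prints

```
R^2 = 0.891, F = 27.16 (p = 7.19e-19), n = 66
```

meaning: across 66 jittered mid-monthly observations the trend +
time-varying seasonal decomposition explains 89% of the variance, and
the seasonal structure is overwhelmingly significant against a
constant-mean model on ~16 effective parameters.  `fit_summary.json`
holds the estimated hyperparameters — here the annual harmonic's noise
variance ratio (≈0.35) is an order of magnitude above the trend's
(≈1e-9), i.e. the cycle drifts while the trend is essentially flat —
and `fit_fit.csv` holds the per-sample trend, seasonal, fitted values
and 95% band.

The EQR stage on the simulated counts:

```sh
diatomseason eqr --counts data/counts.csv --expected-index 25 --out eqr
```

```
status
high        24
good        22
moderate    20
```

— the synthetic community cycles through status classes with season, the
qualitative pattern the decomposition then quantifies.  The same chain
runs end-to-end from one config with
`diatomseason run-all --out rundir` (counts → EQR → ASDHR; sensors →
antecedent windows → PCA), writing per-stage CSVs, `summary.json`, a log
and a config snapshot.

The equivalent library calls:

```python
from diatomseason import gen_eqr_series, fit_asdhr, confidence_band

series, truth = gen_eqr_series(seed=1)        # 66 obs, 5.5 years
fit = fit_asdhr(series)                        # period 1 yr, 2 harmonics
band = confidence_band(fit, 0.95)
print(fit.r_squared, fit.f_pvalue)
```

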