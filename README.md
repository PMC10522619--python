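# habforecast

Hybrid **EEMD–MLR–LSTM** forecasting of multichannel fluorometer time
series, for harmful-algal-bloom (HAB) early warning at aquaculture sites.

A moored three-channel fluorometer reports chlorophyll-a fluorescence at
470 nm and 530 nm excitation (µg/L) and turbidity every 10 minutes; sparse
laboratory phytoplankton counts (cells/mL) arrive at irregular instants.
This package forecasts the sensor channels a few hours ahead and converts
those forecasts into a phytoplankton-abundance forecast — the quantity a
farm manager needs in order to act before a bloom peaks.  It is written for
aquatic-monitoring scientists and engineers who have gappy, spiky,
non-stationary sensor records and not much labelled biology.

## The method

Each cleaned channel x(t) is decomposed by **ensemble empirical mode
decomposition** into intrinsic mode functions and a residue,

    x(t) = Σᵢ IMFᵢ(t) + R(t),

where each EMD trial sifts components through cubic-spline envelope
subtraction and the ensemble (M noisy trials, white Gaussian noise at
0.2·std(x)) is averaged component-wise.  Every IMF and the residue gets its
own **stacked LSTM** (the usual gate algebra: C_t = F⊙C_{t−1} + I⊙G,
h_t = O⊙tanh C_t), trained on the min-max-normalized component;
de-normalized component forecasts are summed back into a channel forecast.
**Multivariate linear regression** fitted on the training split,

    Y = β₀ + β₁·CHL470 + β₂·Turbidity + β₃·CHL530 + ε,   β̂ = argmin‖Y − Xβ‖²,

maps channel forecasts X_f to the phytoplankton forecast Y_f = X_f β̂.
Accuracy is reported as MAE, MSE, RMSE and MAPE against the held-out
chronological 25 %, with plain-LSTM and last-value-persistence baselines
run under identical splits and budgets.  Because the field data behind the
method are proprietary, the package ships a synthetic generator that
reproduces their statistical regime (diurnal + tidal oscillations over a
trend, AR(1) sensor noise, strongly coupled channels, weakly coupled lab
counts, dropouts and biofouling-like spikes) with full ground truth.

## Worked example

```python
from habforecast import (SyntheticConfig, generate, clean_dataset,
                         correlation_matrix, PipelineConfig, HybridEEMDLSTM)

dataset, truth = generate(SyntheticConfig.scenario(seed=7))   # 40 days, 10-min cadence
cleaned, report = clean_dataset(dataset)                      # impute, de-spike, smooth
print(correlation_matrix(cleaned).to_frame().round(3))

results = HybridEEMDLSTM(dataset, PipelineConfig.fast(seed=7, max_origins=20)).fit()
print(results.summary())
```

prints

```
               chl470  chl530  turbidity  phytoplankton
chl470          1.000   0.931      0.956          0.290
chl530          0.931   1.000      0.941          0.317
turbidity       0.956   0.941      1.000          0.301
phytoplankton   0.290   0.317      0.301          1.000

Hybrid EEMD-MLR-LSTM forecast results
  mode: honest   decompose: True   horizon: 6 steps   origins: 20
  train/test boundary: sample 720
  series               MAE           MSE        RMSE      MAPE
  chl470           0.75831      0.780259     0.88332    0.1115
  chl530            0.5919      0.546721     0.73941    0.1259
  turbidity         1.0961       1.77713      1.3331    0.1088
  pooled           0.81543        1.0347      1.0172    0.1154
  dependent         428.38        256861      506.81    0.3699

Channel regression (OLS)
  observations: 35    R^2: 0.1394    residual variance: 147059
  term                  coef       std err
  intercept          497.244       530.969
  chl470             22.2354       219.593
  chl530              209.84        214.62
  turbidity         -60.1669       187.363
```

Reading it: the two chlorophyll excitations and turbidity are almost
interchangeable (r ≳ 0.93 — they watch the same biomass), while the lab
counts correlate weakly (r ≈ 0.3 — sampling noise and patchiness), which is
exactly why the dependent forecast goes through a regression rather than a
direct model.  Six-hour channel forecasts come in around 11–13 % MAPE on
the held-out quarter; the wide coefficient standard errors are the expected
signature of collinear channels and 35 training counts, so coefficient
checks are stated in standard-error units, not absolute ones.

A `habforecast` command-line tool wraps the same library
(`simulate`, `clean`, `correlate`, `decompose`, `fit`, `forecast`,
`evaluate`, `run`), configured by one small YAML file; see
`habforecast --help`.

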