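# phenoscale

Cross-scale plant phenology modeling: do models of spring events (budburst,
flowering) fit to intensive single-site monitoring agree with the same models
fit to sparse, broad-scale citizen-science style observations?

`phenoscale` provides, as scikit-learn style estimators, eight phenology
models; the cleaning rules that turn repeated yes/no phenophase status
records into inferred event dates; global model fitting by differential
evolution with bootstrap uncertainty; the statistics for comparing two
fitted-model collections; and a synthetic-data generator that emulates the
two observation regimes so the whole experiment runs end to end with no
external data.

## The models

Six of the eight are thermal-forcing models: daily mean temperature *Tᵢ* is
transformed by a forcing function *R_f*, accumulated from a start day, and
the event is predicted on the first day of year (DOY) where

∑ₜ₌ₜ₁^DOY R_f(Tᵢ) ≥ required forcing.

| model | requirement | R_f(Tᵢ) | parameters |
|---|---|---|---|
| Naive | — (constant mean DOY) | — | 1 |
| Linear | DOY = β₁ + β₂·T̄_spring | — | 2 |
| GDD | F\* from t₁ | max(Tᵢ − T_base, 0) | 3 |
| Fixed GDD | F\* from 1 Jan | max(Tᵢ, 0) | 1 |
| Alternating | a + b·e^{c·NCD(t)} from 1 Jan | max(Tᵢ − 5, 0) | 3 |
| Uniforc | F\* from t₁ | 1/(1 + e^{b(Tᵢ − c)}) | 4 |
| M1 | (L/24)ᵏ·F\* from t₁ | max(Tᵢ − T_base, 0) | 4 |
| MSB | a + b·e^{c·NCD(t)} + d·T̄_spring | max(Tᵢ − 5, 0) | 4 |

NCD(t) is the running count of chill days (mean temperature below 0 °C
since 1 January), L the photoperiod in hours, and T̄_spring the 1 January –
31 March mean temperature. All models are fit by differential evolution
minimizing the RMSE of predicted event DOY, with 250 bootstrap refits for
parameter uncertainty; predictions default to the mean of the per-bootstrap
predicted dates.

## Worked example

Simulate a broad-scale campaign from a known forcing requirement
(F\* = 200 degree-days), clean the status records, and refit:

```python
from phenoscale import (SyntheticConfig, generate_dataset, prepare_events,
                        holdout_split, build_design_matrix)
from phenoscale.models import FixedGDDModel
from phenoscale.fitting import rmse

cfg = SyntheticConfig(n_sites_broad=8, n_sites_intensive=0,
                      years=(2014, 2015, 2016), n_species=1,
                      n_individuals_broad=4, seed=11)
ds = generate_dataset(cfg)
events = prepare_events(ds.status_broad, max_gap_days=30, min_n=10)
split = holdout_split(events, fraction=0.20, seed=11)
X_tr, y_tr = build_design_matrix(split.train_events, ds.temperatures)
X_te, y_te = build_design_matrix(split.test_events, ds.temperatures)

model = FixedGDDModel(n_bootstrap=50, random_state=11).fit(X_tr, y_tr)
print("point F*:", round(model.params_["f_star"], 1))
print("bootstrap mean F*:", round(model.bootstrap_params_.mean(), 1),
      "sd:", round(model.bootstrap_params_.std(), 1))
print("train RMSE:", round(model.rmse_train_, 2))
print("holdout RMSE:", round(rmse(model.predict(X_te), y_te), 2))
```

Output:

```
point F*: 190.4
bootstrap mean F*: 184.2 sd: 8.6
train RMSE: 5.47
holdout RMSE: 3.35
```

The fitted requirement lands near the generating value of 200 degree-days
despite the sparse visit schedule; the few-day RMSE reflects the midpoint
censoring of event dates between visits (mean visit gap ≈ 10 d) plus the
2-day individual noise, not model error.

The full experiment — both observation scales, all models, the three
comparison statistics — runs from a config file:

```bash
phenoscale run-all --config config.yml --seed 42
```

which writes per-model parameter R², prediction R² per evaluation scale,
and holdout RMSE differences with t-tests to
`comparison_report.{csv,json}`.

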