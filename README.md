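# heatlag

Lag-aware machine-learning analysis of summer heat and cardiovascular
mortality risk, with transfer learning for warming-climate projection.

Hot summer days raise deaths from ischaemic heart disease, and the effect is
not instantaneous: risk stays elevated for about a week after a hot day, and a
season's accumulated heat load modulates it (heat acclimatisation).  This
package is for epidemiologists and climate–health modellers who want that
whole chain — from lag inference to future-climate risk percentiles — as
tested, seeded, reusable code.  Because the underlying mortality and gridded
weather records of such studies are typically restricted-access, the package
ships a synthetic two-city generator with recorded ground truth, so every
stage is verifiable end to end on a desk.

## The model chain

1. **Daily relative risk (DRR).**  `DRR_t = ND_t / mean(ND over the same
   year's July–August days)`; each season averages to 1 exactly, removing
   slow demographic drift.
2. **Distributed lag nonlinear model (DLNM).**  A quasi-Poisson regression
   `log E[ND_t] = α + cb(x, ℓ)_t + ns(date, df × year)` where `cb` is the
   tensor product of natural cubic bases over the exposure (df 2) and lags
   0–14 (df 2), fitted by IRLS.  The fitted exposure–lag–response surface
   `RR(x, ℓ)`, centred at the median exposure, is reduced to an integer
   "lag days" per weather element by a contiguous-significance rule at the
   95th-percentile exposure.
3. **Feature table.**  Per element with lag N: `E, EPre2..EPreN,
   EDiffPre1..EDiffPreN`, plus the accumulated heat
   `AcTmax30_t = Σ_{i≤t} max(Tmax_i − 30, 0)` (season-reset), rainfall and
   day-of-week.
4. **Boruta-SHAP selection.**  Shadow (permuted) copies of all features are
   added; features repeatedly beating the best shadow by mean |SHAP| under a
   gradient-boosted regressor are accepted by a binomial test, rejected
   features are iteratively removed.
5. **Boosted hindcast.**  LightGBM regression of DRR with 10-fold CV,
   `num_leaves` tuned over 10–100; skill is reported as out-of-fold
   RMSE, MAE and RMSE/MAE.
6. **SMOGN + transfer learning.**  Rare high-DRR days (upper 10%) are
   over-sampled 1.3-fold by neighbour interpolation/Gaussian perturbation;
   a hotter source city is pooled via feature augmentation
   `Φs(x) = ⟨x, x, 0⟩`, `Φt(x) = ⟨x, 0, x⟩` so one learner shares and
   specialises effects across domains.
7. **Projection.**  Trained models predict DRR under low/middle/high warming
   offsets; the shift is summarised as future/present percentile ratios
   (95th, 99th) against both the model's present-era simulation and the
   actual DRR.

## Worked example

```python
import heatlag as hl

sc = hl.ScenarioConfig(seed=0)                      # 11 synthetic summers
weather = hl.generate_weather(sc, "target")
deaths, truth = hl.generate_mortality(weather, sc)

fit = hl.fit_dlnm(weather["tmax"], deaths["count"], weather["date"])
decision = fit.specify_lag_days()
print(f"dispersion: {fit.dispersion:.3f}")
print(f"Tmax lag days: {decision.lag_days} (significant: {decision.significant})")

drr = hl.compute_drr(deaths)
table = hl.build_feature_table(weather, hl.LagSpec(tmax=decision.lag_days))
y = drr.merge(table[["date"]], on="date")["drr"].to_numpy()

selection = hl.run_boruta_shap(table.drop(columns=["date"]), y, n_trials=40, seed=0)
print("accepted features:", selection.accepted)

model = hl.tune_and_fit(table.drop(columns=["date"])[selection.accepted], y, seed=0)
m = model.metrics_
print(f"hindcast RMSE {m['rmse']:.3f}  MAE {m['mae']:.3f}  RMSE/MAE {m['ratio']:.3f}")
```

prints

```
dispersion: 0.997
Tmax lag days: 7 (significant: True)
accepted features: ['Tmax', 'VapPre3']
hindcast RMSE 0.320  MAE 0.253  RMSE/MAE 1.266
```

The dispersion near 1 says the synthetic counts are Poisson-consistent; the
lag rule recovers roughly the one-week lag profile that generated the data;
selection keeps temperature-driven features (vapor pressure is coupled to
temperature in the generator) and rejects rainfall; and the out-of-fold
hindcast error is about a quarter of the seasonal mean risk, with RMSE/MAE
close to 1.27 — errors only mildly heavy-tailed.

The same chain, plus SMOGN/transfer training and the warming projection, runs
as one pipeline:

```bash
heatlag run --out runs/demo            # or: heatlag simulate|dlnm|features|select|train|adapt|project
```

which writes every intermediate artifact (CSV/JSON/YAML), a run manifest with
config hash and artifact digests, and a log; runs with the same config and
seed are byte-identical.

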