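# Methods

`heatlag` implements a complete lag-aware analysis chain for weather-sensitive
summer cardiovascular mortality: a distributed lag nonlinear model (DLNM) that
decides how many lag days of each weather element matter, a lag-expanded
feature table around the daily relative risk (DRR), Boruta-SHAP feature
selection, a cross-validated gradient-boosted hindcast, SMOGN over-sampling
with feature-augmentation transfer learning, and a warming-scenario percentile
projection.  Everything runs on a seeded synthetic two-city scenario with
recorded ground truth, so each stage can be tested against what actually
generated the data.

## The response: daily relative risk

For day *t* in year *y*, `DRR_t = count_t / mean(count over year y's July–August
days)`.  Each season's DRR averages to exactly 1 (enforced to 1e-9), which
removes year-to-year drift from population aging and medical progress and makes
seasons comparable across a decade.  A season with zero total deaths cannot be
normalised and raises an error naming the year.

## Synthetic study conditions

The generator emulates an 11-year (2009–2019) July–August record for two
cities, with the source city running ~1 °C hotter at the 50th and 95th Tmax
percentiles than the target city.  Per season, daily maximum temperature is a
smooth seasonal curve (mean 31 °C, amplitude 1.5 °C, peaking mid-season) plus
stationary AR(1) noise (sd 2.2 °C, lag-1 coefficient 0.6) restarted each season
— only July–August is modelled, so no cross-winter continuity is claimed.
Vapor pressure is affine in Tmax (6 hPa + 0.65 hPa/°C, noise sd 1.2 hPa;
summer means ≈ 26 hPa), air pressure is an independent AR(1) around 1009 hPa,
and rainfall is zero-inflated exponential (65% dry days, mean wet-day 8 mm).
Every draw is keyed by `(seed, city, year)`, so extending the record never
perturbs earlier years.

Death counts are Poisson with

    log mu_t = log(10) + 0.08 · Σ_l w_l · max(Tmax_{t−l} − 30, 0)
             + (−0.001) · min(AcTmax30_t, 130)

* The hinge at 30 °C reproduces the observed exponential risk increase above
  ~30 °C on the log scale.
* The lag profile `w_l` decays exponentially over lags 0–7 (ratio 0.6,
  normalised to sum 1): heat effects on cardiovascular mortality are largest
  same-day and fade over about a week, which is also why the same-day and
  short-lag temperature features dominate downstream selection.
* `AcTmax30` is the within-season running sum of exceedances above 30 °C
  (°C-days); its negative coefficient emulates heat acclimatisation.  The term
  saturates at 130 °C-days because physiological adaptation to heat load
  levels off; an unbounded linear penalty would make sufficiently warm futures
  *protective*, which is not the regime being modelled.
* Lags reaching before the season start are padded with the season's first
  observed value so the mortality and weather date sets stay equal; the
  feature table instead *drops* early-season rows (observed values only).

Future weather shifts Tmax by a low/middle/high warming offset (defaults +1,
+2, +3 °C, emulating the spread of three global climate models under a
high-emissions pathway) plus fresh AR(1) noise (sd 0.5 °C), re-derives vapor
pressure through the coupling, and relabels dates 36 years later.

What the generator does **not** emulate: spatial weather structure, holidays,
influenza or pollution confounding, age-structured population change, and any
real-city calibration beyond the ordering/offset properties above.  Passing
tests therefore demonstrate the machinery recovers known structure under
these idealised conditions, not that the effect sizes transfer to real data.

## DLNM lag analysis

The count model is `log E[ND_t] = intercept + crossbasis(Tmax, lag)_t +
trend(date)_t` with a quasi-Poisson error.  The cross-basis is the tensor
product of a natural cubic basis over the exposure (df 2, knots equally spaced
over the observed range) and a natural cubic lag basis over lags 0–14
(df 2, intercept included).  A natural cubic spline on K knots spans exactly K
functions including the constant, so at df 2 the lag margin has boundary knots
only and degenerates to {1, lag}; interior knots — placed at equal intervals on
the log(lag+1) scale so lag 0 is admissible — appear only at df ≥ 3.  The
result is a 4-column cross-basis whose row *t* depends only on same-season
exposures at days t−0..t−14 (season-padded like the generator).

The long-term trend is a natural cubic spline on the running day index with
2 df per year (22 df over 11 years), knots at equal quantiles of the in-sample
dates so the spline spans season gaps smoothly.  The index is rescaled to
[0, 1] and the trend block is centred and QR-orthonormalised before fitting —
a pure reparameterisation of the same function space that keeps the design
well conditioned at high df (the cross-basis coefficients are invariant
to it).

Fitting is iteratively reweighted least squares on the Poisson likelihood
(relative deviance change < 1e-8, max 100 iterations; non-convergence raises
with the deviance trace, rank-deficient designs raise immediately).  The
quasi-Poisson dispersion is the Pearson χ²/df and scales only the covariance;
point estimates equal Poisson maximum likelihood, which the tests verify
against both an independent trust-region optimizer of the likelihood and a
reference GLM implementation.

Relative-risk surfaces are centred at the per-series **median** exposure
(RR ≡ 1 there by construction), with delta-method CIs on the linear predictor
and a lag-cumulative curve that sums log-RR over lags 0–14.  Each of Tmax,
vapor pressure and air pressure is fitted separately, without the other two as
confounders.

**Lag-day rule.**  At the 95th-percentile exposure, the pointwise 95% CI of RR
is read at each integer lag; the rule returns the last lag of the contiguous
significant run starting at the first significant lag, capped at 14 (a run
persisting to lag 14 returns 14).  If no lag is significant the rule returns
1 **flagged** as non-significant, so lag structure is never claimed silently.
Because 15 correlated pointwise intervals are read, the familywise null flag
rate sits a few points below the pointwise 95% level (≈ 90–97% depending on
the effective degrees of freedom); simulations show ≈ 95% under the null and
recovery of a flat 0–7-day lag profile as 6–10 specified lag days in ≈ 90%
of runs.

## Feature table

For element E with lag specification N (per the DLNM): same-day `E`, lagged
levels `EPre2..EPreN`, lagged differences `EDiffPre1..EDiffPreN` (today minus
n days before), plus `AcTmax30`, `Rain`, and `DOW` (7-level categorical passed
to the tree learner natively, not one-hot).  The level features intentionally
start at Pre2 and the differences at Pre1.  All lagging is within-season; the
first max-lag days of each season are dropped, so no feature ever uses data
after its own day (a corruption test verifies this).  For lags (8, 9, 14) the
full expansion yields 65 columns.  A documented `diff_mode="first"` variant
keeps only the first difference per element, giving the alternative 37-column
layout; an arithmetic audit shows that is the only breakdown of 37 that also
contains all of `TmaxPre2`, `PresPre14` and `PresDiffPre1`.

## Boruta-SHAP selection

Each trial appends an independently row-permuted "shadow" copy of every
feature, fits a LightGBM regressor on the doubled matrix, and scores each
original feature by its mean |SHAP| over training rows, computed with
LightGBM's exact tree-SHAP (`pred_contrib`).  A feature scores a hit when it
beats the **maximum** shadow importance.  Every `test_every = 10` trials,
hit counts are tested against Binomial(n_active_trials, ½), two-sided with
Bonferroni correction across the features still in play (α = 0.05 default):
significantly many hits → accepted; significantly few → rejected and, as in
the original Boruta procedure, removed (with their shadows) before further
trials, so redundant informative features stop being drowned by a large
shadow maximum.  Features still tentative at the trial budget (default 50)
are excluded downstream.  The empty-acceptance case propagates as an explicit
"no important features" error.

## Boosted DRR regression

LightGBM regression of DRR on the selected features with k = 10-fold CV.
Only `num_leaves` is searched (grid 10–100 step 10; ties to the smaller
value); folds are fixed before the search so every grid value sees identical
splits.  Other settings are fixed and documented: 200 trees, learning rate
0.05, `min_child_samples` 10, single-threaded deterministic row-wise mode so
repeated runs are byte-identical.  Folds are random day-level partitions by
default with a `fold_scheme="by_year"` switch for temporal blocking.  The
hindcast is the concatenated out-of-fold predictions — the honest reading of
skill, since every day is predicted by a model that never saw it — and
RMSE/MAE/(RMSE/MAE) are reported on it.  SHAP dependence values are likewise
out-of-fold.  On the default synthetic conditions the hindcast lands at
RMSE ≈ 0.32–0.35, MAE ≈ 0.26–0.28, ratio ≈ 1.24–1.29.

## SMOGN and transfer learning

Rare high-risk days are the rows with DRR at or above the 0.90 quantile (a
hard threshold, matching the "upper 10%" description, rather than a smooth
relevance function).  Each synthetic row interpolates a rare seed row toward
one of its 5 nearest rare neighbours (uniform weight) when the neighbour is
within half the median pairwise rare distance, else perturbs the seed with
Gaussian noise scaled by 0.05 of each feature's sd; the response is
interpolated/perturbed consistently.  The rare count grows to
ceil(1.3 × original) — the 1.3 multiplier mirrors the reported frequency
increase.  Originals are always preserved and synthetic rows are flagged.

Transfer learning is homogeneous feature augmentation: source rows map to
⟨x, x, 0⟩, target rows to ⟨x, 0, x⟩ (3F columns), and one boosted model is
trained on the pooled rows — the hotter city as source, the projected city as
target, with the target block SMOGN-resampled first (the no-TL future model
uses the same resampling without the source domain, so the comparison isolates
the transfer itself).  Prediction for new target days routes through the
target mapping.  Simulations with the target truncated below its 60th
temperature percentile and a +2 °C source show TL beating no-TL on held-out
hot days in ≈ 90% of runs, while identical domains leave TL within a few
percent of no-TL.

## Projection

Each trained variant predicts the future daily DRR from feature tables built
on the warmed weather (fold-averaged across the k models).  Percentiles use
linear interpolation between order statistics (stated in the output
metadata).  Ratios are reported against two present-era baselines: the
variant's **own** present-era prediction series, and the actual DRR.  Using
the variant's own present simulation — rather than the plain hindcast —
isolates the climate signal from model recalibration (SMOGN and TL shift the
prediction scale), and makes the identity scenario (zero offset, zero noise)
return ratios of exactly 1.

Two honest limitations of this projection style are worth stating.  Trees
cannot extrapolate: predictions clamp at the edge of the training support, so
future ratios understate the ground-truth tail amplification (this is
precisely the motivation for SMOGN and the hotter-source transfer, which
extend the learned support).  And when the accumulated-heat feature is in the
model, warming shifts hot days toward high-accumulation (penalised) regions,
which can offset the temperature signal at the extreme tail; the monotonicity
of percentile ratios in the warming offset is therefore a property of the
temperature-level channel, and is tested as such.

## Problem sizes and reproducibility

The shipped demonstration configuration uses the full 11-year two-city
scenario (682 in-season days per city) for the pipeline and acceptance
script, with 40 selection trials and the full leaves grid; the test suite's
reduced demonstration run uses 8 years, 20 trials and a 3-point grid.
Simulation-based checks use 20 seeds (100 for the null flag rate).  All
randomness flows from a single integer seed through named substreams; two
runs with the same configuration and seed produce byte-identical artifacts,
and a machine-readable manifest records the configuration hash, seeds,
library versions and artifact digests.
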