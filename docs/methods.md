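# Methods

`cropclimex` implements an end-to-end analysis of how co-occurring hot-dry
(and cold-wet) growing-season extremes relate to crop yield anomalies, and
of how the probability of such compound seasons changes over a multi-decade
record. Because the analysis chain is exercised on synthetic gridded data
with known effect sizes, every stage can be validated by parameter
recovery rather than by comparison with restricted-access observational
archives.

## The analysis chain

**Indicators.** For each grid cell, harvest year and water regime
(irrigated/rainfed) the daily weather inside the 90-day pre-harvest window
is reduced to histograms: sub-daily temperature (24 samples/day from a
sinusoidal diurnal cycle between tmin and tmax, in 0.1 °C bins over
−20…60 °C) and daily soil-moisture deficit (the rescaled complement of
volumetric soil moisture, in 0.001 bins over 0…1). Regime histograms are
merged with harvested-area weights. Extreme-day counts are read against
percentile thresholds of the cell's pooled all-years within-season
distribution: hot/dry days lie above the 90th percentile of temperature /
deficit, cold/wet days below the 10th. Seasonal means of temperature and
soil moisture and precipitation totals over the window and over the 365
days preceding harvest complete the indicator table. Seasons whose window
(or annual precipitation window) would precede the record start — in
practice the first year — are dropped.

**Features and response.** Yields are de-trended per cell with a centered
5-year moving average (truncated at the edges so all years keep a value)
and expressed as proportional anomalies (y − MA)/MA. Indicator columns are
z-scored per cell (sample sd, n−1; numerically constant columns map to
zero). Dry- and wet-day counts are square-root transformed before
z-scoring to de-skew them; the four average-condition variables are
OLS-de-trended on year first. Extreme-day counts are *not* de-trended in
the main configuration (a flag enables it as a sensitivity). Cells are
grouped into 25 climate bins by nested quintiles of climatological
growing-season temperature and annual precipitation, with precipitation
quintiles computed within each temperature quintile and ties broken by
cell id.

**Yield model.** Gradient-boosted regression trees (squared-error
objective, ≤ 400 trees, depth 3, learning rate 0.1). Years are randomly
split into four groups; each fold trains on two groups, uses one for early
stopping (40 rounds without improvement of evaluation RMSE) and predicts
the held-out group, so every prediction is out of sample with respect to
its year. Four regularization hyperparameters (subsample 0.5–1, feature
fraction 0.5–1, L2 penalty 0.5–1.5, split-gain penalty 0–0.05) are chosen
by randomized search (5 draws) with year-disjoint 3-fold CV on the
training rows (RMSE; ties keep the first draw). The whole procedure is
repeated with re-randomized splits (default 10 repeats at desk scale;
set `n_repeats=100` for the full protocol); the repeat distribution of any
downstream statistic provides the 2.5–97.5 percentile confidence interval.
Skill is the sign-preserved squared Pearson correlation between reported
and predicted anomalies aggregated to (area-weighted) yearly means;
feature attribution uses TreeSHAP (exact additive Shapley values for tree
ensembles, checked against the additivity identity).

**Impacts.** Scenario responses are brute-force partial dependences: the
standardized hot/dry (or cold/wet) day-count columns are fixed at chosen σ
values (−2.25…2.25 in 0.25 steps; compound scenarios fix both at 1.5σ), a
seeded sample of 1000 training observations supplies the other columns,
and the mean model output — in percent yield anomaly — is averaged over the
four folds of each repeat. σ values are injected into the final
(sqrt-transformed, z-scored) columns, since those are the modelled
features. Bin-level maps report the repeat mean with a zero rule: an
estimate whose 95% CI straddles zero is mapped to exactly zero.

**Trends.** A cell-year is a compound hot-dry (cold-wet) event when both
standardized day-count anomalies are ≥ 1.5σ (inclusive). Event probability
is regressed on midpoint-centered year by maximum-likelihood logistic
regression, each year-cell pair one observation (unweighted; an
area-weighted variant exists but is off by default). The per-year odds
ratio exp(slope) is reported only if three tests all reject at 0.05:
likelihood-ratio vs intercept-only, Wald on the slope, and a bootstrap of
the observations (N = 100; two-sided sign-crossing p with a +1/(N+1)
correction so p is never exactly 0 and the smallest attainable p is
≈ 0.02, which makes the bootstrap the most conservative of the three
gates). Otherwise the reported odds ratio is 1 (no trend). Complete
separation is caught and reported as a gated fit with a flag rather than
an error. Companion outputs: fitted and empirical annual event
frequencies (with a centered 5-year mean), a bootstrap envelope of fitted
probability curves, and a log-odds linearity diagnostic over five
temporally contiguous year blocks (0.5 continuity correction on counts so
event-free blocks stay finite).

## The synthetic world

The generator produces the statistical structure the analysis assumes,
with every random stage drawing from its own substream of the master seed:

- **Temperature**: per-cell base level (spread 12–28 °C across cells so
  climatological binning has distinct values), a sinusoidal seasonal cycle
  (amplitude 8 °C), iid Gaussian daily anomalies (sd 3 °C), and a per
  cell-year mean anomaly (scale 0.33 of the daily sd ≈ 1 °C) representing
  interannual variability of the seasonal state. Without that component
  seasonal means would be unrealistically stable (sd ≈ daily sd/√90
  ≈ 0.3 °C) and would act as noise-free detectors of any seasonal shift.
  tmin/tmax bracket the mean by a stochastic diurnal range (8 ± 1 °C).
- **Soil moisture**: Gaussian daily anomalies coupled to the temperature
  anomaly through a bivariate normal (correlation −0.6 by default), an
  independent interannual component, clipped to [0, 1] m³/m³.
- **Compound events**: per cell-year flags drawn from a logistic model in
  (midpoint-centered) year with slope 0.08 log-odds/yr and midpoint
  probability 2.5%, plus a shared annual log-odds shock (sd 1.25)
  emulating the spatial coherence of extremes — some years are
  compound-prone almost everywhere, so the global event fraction
  fluctuates strongly between years rather than tracking the trend
  smoothly. The shared shock makes the generative model a mixed logistic
  regression; an ordinary logistic fit targets the *marginal* slope, which
  carries the standard logit-normal attenuation factor
  1/√(1 + c²σ²), c = 16√3/(15π) (exposed as
  `SyntheticConfig.marginal_trend_logodds_per_year`, ≈ 0.065 at the
  defaults).
- **Event expression**: a flagged season carries a contiguous 21-day
  hot-dry spell (daily anomalies shifted by +2.5 sd temperature, −2.5 sd
  soil moisture) at a random position inside the season window. A spell —
  rather than a season-long offset — moves the extreme-day counts much
  more than the seasonal means, and its strength is set so flagged seasons
  typically exceed the joint 1.5σ day-count anomaly used by the event
  coding.
- **Yields**: base 4 t/ha, multiplicative management trend (1%/yr),
  a multiplicative penalty (default 10%) applied exactly when the season
  is flagged, and iid multiplicative noise (sd 3%).
- **Calendar**: per-cell harvest days of year; rainfed harvest lags
  irrigated by 10 days; one cell always harvests at DOY 45 so its window
  crosses the year boundary; harvested-area fractions sum to 1 per cell.

What the generator does **not** emulate: spatial correlation of daily
weather between cells, autocorrelated (red-noise) daily anomalies,
precipitation–soil-moisture coupling (precipitation is independent
occurrence/amount noise), multiple cropping seasons, irrigation feedback
on soil moisture, or any geographic physics. Passing tests therefore
demonstrate that the *pipeline* recovers known effect sizes under the
assumed statistical structure — not that the structure matches any
particular real region.

## Numerical and design choices

- Histogram bins are half-open [lower, upper) with the final bin closed;
  out-of-range values clamp to the terminal bins, so total day mass is
  conserved. Extreme-day counting excludes the threshold bin itself
  (symmetric treatment of both tails); the pooled-percentile threshold is
  the first bin at which the cumulative mass fraction reaches q/100.
- The deficit reference min/max is per grid cell over the full record
  (soil conditions differ between cells; a global option exists).
- The temperature percentile pool uses the sub-daily samples by default; a
  daily-means option exists.
- z-scores use the sample (n−1) sd. Constant columns (including exact-fit
  OLS residues below 1e-9 relative) map to zero rather than amplified
  rounding noise.
- Early stopping counts 40 rounds without improvement over the best
  evaluation score (a literal run of 40 strictly increasing errors is
  near-unreachable under stochastic subsampling).
- The tuning metric is RMSE, matching the squared-error training
  objective.
- Scenario sampling is without replacement, re-drawn per repeat from each
  fold's training rows, seeded.
- The bootstrap trend p-value uses the +1/(N+1) correction; the year
  covariate is centered at the series midpoint (affects the intercept
  only, not the odds ratio).

## Problem sizes and variability

Desk-scale defaults (50 cells × 30 years, 10 repeats for the pipeline
runner; 200 cells × 30 years, 20 repeats for the reproduction script and
the recovery tests) keep a full run in the order of a minute while leaving
all effect sizes detectable. With ~29 usable years, the globally
aggregated skill statistic rests on ~29 yearly points whose signal
variance is dominated by a handful of strong compound years; the global
signed r² therefore varies substantially between world realizations
(seeds), which is also why the repeat-level confidence intervals are wide.
The compound partial dependence at 1.5σ is attenuated relative to the
injected penalty: the model spreads the event signal across all correlated
indicators (means, cold/wet counts), while the scenario fixes only the
hot/dry columns — the compound estimate still dominates both single-extreme
responses, which is the property the analysis relies on.

## Limitations

- Tree-based partial dependence at σ values outside the bulk of the
  training distribution (|σ| ≳ 2) saturates at the outermost split
  thresholds.
- The logistic trend model assumes independent observations;
  the shared annual shocks in the synthetic world induce overdispersion,
  so p-values are anti-conservative in that regime (the bootstrap gate
  absorbs part of this).
- The 5-year moving-average de-trending attenuates any low-frequency
  component of a genuine weather-yield signal, not only management trends.
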