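# Methods

This note documents the procedures implemented in `ecoforce`, the default
parameter choices and their rationale, what the synthetic weather
generator emulates, the numerical conventions, and known limitations.

## 1. Model evaluation and selection

### Skill metrics (`ecoforce.skill_metrics`)

Model and observed daily series are paired on their common dates (inner
join after dropping missing values); a pairing that loses more than 20 %
of the overlap raises an error rather than silently scoring a fragment.

- **Mean bias** — mean(model) − mean(obs). For precipitation it is also
  expressed in mm/yr by multiplying the daily bias by 365.25.
- **Perkins skill score (PSS)** — the overlap of the two empirical
  distributions: Σ min(f_model, f_obs) over shared bins. 1 means
  identical distributions, 0 disjoint. Default bin widths: 1 °C for
  temperatures, 1 mm for precipitation, 5 % for relative humidity,
  1 m/s for wind. Precipitation uses a dedicated first bin [0, 0.1) mm so
  the zero-inflation (dry days) is compared explicitly rather than
  smeared into the first regular bin.
- **Seasonal-cycle MAE** — mean absolute difference of the twelve
  monthly climatological means. Any calendar month absent from the data
  is an error, not a silent skip.
- **Percentile MAE** — mean absolute difference at the 1st, 10th, 90th
  and 99th percentiles (linear-interpolation quantiles), summarising
  distribution-tail agreement; a warning is issued below 100 paired days.
- **RMSE** and **Spearman rank correlation** of paired daily values —
  only meaningful for runs driven by reanalysis boundary conditions,
  where model and observed weather are in day-to-day correspondence.
  `skill_table(..., daily_comparable=False)` omits them (and the Brier
  score) for GCM-driven runs, whose internal variability is free-running.
- **Brier skill score (BSS)** — observed days are split into K = 3
  equiprobable categories bounded by the observed climatological
  terciles; the model "forecast" deterministically assigns probability 1
  to the category its own value falls in, and is scored against the
  uniform 1/K climatological reference: BSS = 1 − BS/BS_ref. Values equal
  to a category edge belong to the upper category (half-open bins).
- **Cross-variable correlations** — Pearson correlations between every
  pair of forcing variables, annually and for DJF/JJA, compared between
  model and observations; physical consistency across variables matters
  for an ecosystem-level experiment as much as per-variable skill. DJF
  groups December with the following January–February, dropping the final
  year's December.

### Climate diagnostics (`ecoforce.climate_indices`)

ETCCDI-style indices complement the per-day metrics: diurnal temperature
range (annual/DJF/JJA), wet days (> 0.1 and > 1 mm), frost days
(Tmin < 0 °C), summer days (Tmax > 25 °C), R10mm, Rx1day (mean over the
period of monthly 1-day maxima), consecutive dry/wet days (CDD: < 1 mm,
CWD: ≥ 1 mm, spells truncated at year boundaries), growing season length
(GSL: from the first 6-day span with Tmean > 5 °C to the day before the
first post-July-1 6-day span below 5 °C), PRCPTOT, TXx and TNn. Indices
require whole calendar years unless explicitly allowed otherwise.

### Ranking and selection (`ecoforce.model_selection`)

Within each (variable, metric) cell, runs are ranked 1 (best) to N with
an orientation per metric: absolute value for biases, lower-is-better
for error metrics, higher-is-better for skill scores. Ties keep first
occurrence order (stable sort), so rankings are reproducible. The
composite score is the (optionally weighted) mean rank over available
cells; runs missing a cell are averaged over what they have, with weights
renormalised. The shortlist is the N best composite scores after
explicit exclusions (e.g. runs with known regional artefacts).

The representativeness screen places each shortlisted run's
horizon-mean warming anomaly inside the scenario ensemble: the ensemble
members' horizon means are sorted and assigned positions 100·i/(n−1);
the candidate's percentile is linearly interpolated between them. Runs
outside the central band (default 25–75) are eliminated; if the band
empties the candidate set, it widens symmetrically in 5-point steps
until at least one run survives (never silently returning an
unrepresentative extreme). Among survivors, the run with minimum
absolute precipitation bias is selected — precipitation is typically the
worst-simulated forcing variable and the experiment's water budget is
most sensitive to it.

## 2. Warming-level windows (`ecoforce.gmt_windows`)

Annual GMT is smoothed with a 30-year running mean — the standard
climatological averaging period, long enough to suppress interannual
variability while retaining the forced trend. The window is centred; the
even remainder is split toward the past (year y averages y−15 … y+14),
and years whose window is incomplete are omitted rather than padded. The
anomaly subtracts the plain mean of the 1951–1955 reference years. The
crossing year for a threshold is the first year whose anomaly attains
(≥) the threshold; threshold 0 maps by convention to the reference
midpoint (1953), giving the historical baseline window. Extraction
windows are 5 years centred on the crossing year (start = crossing − 2).
Five years balances sampling of interannual variability against the
warming trend *within* the window; `window_length_sensitivity` quantifies
how the climatological indices of the window change with lengths 1–20.

For a linear GMT trend *a* with no noise, the implemented running mean
gives anomaly(y) = a·(y − midpoint − 0.5): the half-year offset is the
exact consequence of the even 30-year window splitting 15/14 around y.
Combined with the attainment rule this detects crossings one year later
than the idealised continuous-time value midpoint + threshold/a; the
offset is deterministic and within the ±1-year granularity inherent to
annual series.

## 3. Forcing assembly (`ecoforce.forcing_builder`)

From 3-hourly model output to 30-minute facility forcing:

- **State variables** (temperature, pressure, humidity, wind) are
  linearly interpolated; the interpolant passes exactly through every
  3-hourly knot, and the tail after the last knot of the final day is
  held constant so every day has 48 steps.
- **Precipitation** is an accumulated flux, not a state: each 3-hour
  amount is spread uniformly over its six half-hours. The last sub-step
  takes the remainder v − 5·(v/6) so each knot's sum is bit-exact;
  window totals are verified with compensated summation (relative error
  ≤ 1e-12 in tests).
- **Drizzle accumulation** — sub-threshold amounts are postponed: while
  the running buffer plus the step amount stays below 1 mm, the step
  emits 0; once the accumulated total attains 1 mm it is released in
  full at that step. Every delivered event is therefore at least 1 mm —
  the smallest depth the facility's irrigation hardware can deliver —
  and the terminal buffer is reported in the table's metadata, never
  dropped. 1 mm is a hardware property, not a tunable constant.
- **Surface pressure** is reduced hydrostatically from mean sea-level
  pressure: p = mslp·exp(−g·z/(R_d·T)), with g = 9.80665 m/s²,
  R_d = 287.05 J/(kg·K), the concurrent air temperature, and a default
  site elevation of 43 m.
- **Humidity** — model specific humidity is converted to the relative
  humidity the facility controls via the Magnus saturation vapour
  pressure e_s = 611.2·exp(17.62·T/(243.12 + T)) Pa and ε = 0.622.
  Values above 100 % (possible from interpolation and the model's own
  moisture physics) are clipped and logged. The conversion and its
  inverse roundtrip to < 1e-6 relative error.
- **Greenhouse gases** (CO₂, CH₄, N₂O) are annual step functions from a
  concentration table; a window year missing from the table is an error.

## 4. The synthetic weather generator

`ecoforce.synthetic_weather` exists so the full pipeline can be run and
validated at desk scale. It emulates the statistical structure the
pipeline relies on, not any particular climate:

- **Temperature** — an annual harmonic (coldest in mid-January, default
  mean 10 °C, amplitude 7.5 °C, typical of a temperate maritime site)
  plus AR(1) anomalies (autocorrelation 0.7, matching the few-day
  persistence of synoptic weather; stationary sd 2 °C). Tmin/Tmax are
  placed DTR/2 (default DTR 8 °C) below/above Tmean with small jitter,
  clamped so Tmin ≤ Tmean ≤ Tmax always holds.
- **Precipitation** — a 2-state Markov occurrence chain (p01 = 0.4,
  p11 = 0.6, stationary wet-day frequency 0.5) with gamma amounts
  (shape 0.8 < 1, reproducing the dominance of small events;
  scale 5 mm ⇒ ≈ 730 mm/yr, a typical Western European total).
- **Humidity** is a clipped harmonic around 80 %, **wind** Weibull
  (shape 2, scale 4.5 m/s, a standard fit for mid-latitude surface wind).
- **Sub-daily structure** — a diurnal cosine peaking at 15:00 local time
  between daily Tmin and Tmax; daily precipitation split over the eight
  3-hour steps with gamma(0.3) weights (intermittency) while conserving
  the daily total exactly; mean sea-level pressure as a stationary AR(1)
  around 101325 Pa (autocorrelation 0.98, stationary sd ≈ 750 Pa,
  synoptic-like); specific humidity back-computed through the Magnus
  relation so the humidity conversion roundtrips.
- **Biased "model runs"** are independent draws plus prescribed additive
  temperature bias, multiplicative precipitation factor, humidity offset,
  wind factor and variance inflation — so the evaluation step has a
  known ground truth. A linear warming trend produces scenario-style
  runs.
- **GMT trajectories** are linear trends plus optional Gaussian noise.

All draws flow from fixed, documented sub-streams of a single seed
(`numpy.random.SeedSequence` spawning), so every result in the test
suite and the acceptance script is exactly reproducible.

## 5. Numerical conventions

- Quantiles use linear interpolation between order statistics
  (`numpy` default, type 7).
- Ranking ties keep input order (stable argsort); missing values are
  excluded from ranking, not ranked last.
- Precipitation mass balances use compensated summation (`math.fsum`).
- Comparisons at thresholds: wet day is strictly > threshold; dry spell
  day is < 1 mm, wet spell day ≥ 1 mm; warming crossing is attainment
  (≥).
- Calendars: daily series must form whole calendar years (checked
  calendar-agnostically); CF/NetCDF input honours the file's declared
  calendar (`standard`, `noleap`, `360_day`) and refuses files without
  one.

## 6. Limitations

- **Uniform disaggregation flattens sub-3-hour rain intensity**: a
  convective burst becomes six equal half-hours. The drizzle filter
  restores actionable event depths but not intensity structure.
- **The drizzle filter delays water**: sub-millimetre amounts arrive
  late (and a terminal buffer of up to 1 mm per window is withheld and
  reported, not delivered).
- **Crossing-year uncertainty under GMT noise.** The anomaly reference
  is the *plain* 5-year mean of noisy annual GMT, so its standard error
  (sd/√5) translates into crossing-year uncertainty of (sd/√5)/trend.
  At trend 0.02 °C/yr and noise sd 0.1 °C that is ±2.2 years (1σ) from
  the reference alone — larger than the deterministic part of the
  detection error. A strict ±3-year acceptance check at these settings
  therefore fails occasionally by construction (the corresponding test
  is kept at the strict tolerance and documented as such). Smoothing the
  reference as well would suppress this, at the cost of departing from
  the plain-reference definition.
- **Selection is station-centric**: skill is measured against one
  station; the chosen run is optimal for that point, not the region.
- **The synthetic generator is statistically, not physically,
  consistent**: cross-variable dependencies (e.g. rain–temperature
  coupling) are weaker than reality, so cross-correlation diagnostics on
  synthetic data exercise the code path more than the science.
- Heat fluxes present in sub-daily model output are passed through
  untouched; the package does not model the surface energy balance.
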