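# ecoforce

Climate forcing for controlled-environment (ecotron) experiments from
regional climate model output.

Ecotron facilities enclose intact ecosystem monoliths and prescribe their
full atmospheric boundary conditions — air temperature, precipitation,
humidity, wind, pressure and greenhouse-gas concentrations — at
half-hourly resolution. To expose such an experiment to *future* climate
rather than an arbitrary scenario, `ecoforce` implements a three-step
pipeline that turns an ensemble of regional climate model (RCM) runs into
ready-to-play forcing tables:

1. **Model selection** — score every available RCM run against local
   station observations (mean bias, Perkins skill score, seasonal-cycle
   and percentile errors, RMSE, rank correlation, Brier skill score,
   cross-variable correlations, and ETCCDI-style climate diagnostics),
   rank the runs per variable and metric, shortlist the best performers,
   screen the shortlist for representativeness inside the scenario
   ensemble, and pick the run with the smallest absolute precipitation
   bias.
2. **Warming-level windows** — smooth annual global mean temperature
   (GMT) with a 30-year running mean, express it as an anomaly against
   the 1951–1955 reference, find the first year each warming threshold
   (+1, +1.5, +2, +3, +4 °C) is crossed, and centre a 5-year extraction
   window on that year.
3. **Forcing extraction** — cut the selected run's 3-hourly output over
   each window and convert it to 30-minute facility forcing: linear
   interpolation of state variables, mass-conserving uniform
   precipitation disaggregation, drizzle accumulation so every delivered
   rain event is at least 1 mm (actionable by irrigation hardware),
   hydrostatic reduction of sea-level pressure to site elevation, Magnus
   conversion between specific and relative humidity, and annual
   greenhouse-gas step functions.

The package also contains a stochastic weather generator
(`ecoforce.synthetic_weather`) used to exercise and validate the entire
pipeline without access to multi-terabyte climate archives.

## Worked example

Score three synthetic "model runs" against synthetic observations and
rank them (run `RCM-A/GCM-1` is generated without biases, the other two
with warm/wet and cold/dry biases):

```python
from ecoforce import skill_metrics as sm, model_selection as msel
from ecoforce.synthetic_weather import (BiasSpec, SyntheticClimateSpec,
                                        gen_model_run, gen_station_obs)

obs_spec = SyntheticClimateSpec(seed=11, n_years=10, start_year=1951)
obs = gen_station_obs(obs_spec)
runs = {
    "RCM-A/GCM-1": gen_model_run(obs_spec, BiasSpec(), seed=1,
                                 experiment="evaluation"),
    "RCM-B/GCM-2": gen_model_run(obs_spec, BiasSpec(t_bias=2.0, p_factor=1.4),
                                 seed=2, experiment="evaluation"),
    "RCM-C/GCM-3": gen_model_run(obs_spec, BiasSpec(t_bias=-1.5, p_factor=0.7),
                                 seed=3, experiment="evaluation"),
}
skill = sm.skill_table({k: r.daily for k, r in runs.items()}, obs)
composite = msel.aggregate_ranks(
    msel.rank_skill_table(skill).pivot_table(
        index="run", columns=["variable", "metric"], values="rank"))
print("composite skill rank (1 = best):")
print(composite.sort_values().round(2).to_string())
```

```
composite skill rank (1 = best):
run
RCM-A/GCM-1    1.6
RCM-C/GCM-3    1.9
RCM-B/GCM-2    2.5
```

Find warming-level windows on a noisy synthetic GMT trajectory
(0.02 °C/yr trend):

```python
from ecoforce import gmt_windows as gw
from ecoforce.synthetic_weather import GmtTrajectorySpec, gen_gmt

gmt = gen_gmt(GmtTrajectorySpec(start_year=1921, n_years=240,
                                trend=0.02, noise_sd=0.05, seed=4))
anom = gw.gmt_anomaly(gmt)   # 30-yr running mean vs 1951-1955
for w in gw.windows_for_thresholds(anom, thresholds=(1.0, 2.0, 3.0)):
    print(f"+{w.threshold:g} degC window: {w.start_year}-{w.end_year} "
          f"(crossing {w.crossing_year})")
```

```
+1 degC window: 2003-2007 (crossing 2005)
+2 degC window: 2053-2057 (crossing 2055)
+3 degC window: 2103-2107 (crossing 2105)
```

Extract the half-hourly forcing table for the +2 °C window:

```python
import numpy as np, pandas as pd
from ecoforce import forcing_builder as fb
from ecoforce.containers import GhgTable, ModelRun, WarmingWindow
from ecoforce.synthetic_weather import (SyntheticClimateSpec,
                                        gen_station_obs, gen_subdaily)

daily = gen_station_obs(SyntheticClimateSpec(seed=11, n_years=160,
                                             start_year=1951))
run = ModelRun(rcm_name="RCM-A", gcm_name="GCM-1", experiment="rcp85",
               daily=daily, subdaily=gen_subdaily(daily, seed=5))
years = pd.Index(range(1951, 2111), name="year")
ghg = GhgTable(pd.DataFrame({"co2": 330.0 + 2.0 * np.arange(160),
                             "ch4": 1800.0, "n2o": 330.0}, index=years))
window = WarmingWindow(2.0, 2055, 2053, 2057)
forcing = fb.assemble_forcing(run, [window], ghg)[2.0]
print(forcing[["tair", "precip", "relhum", "surf_pressure", "co2"]]
      .head(4).round(3).to_string())
print(f"rows: {len(forcing)} (5 years x 48 half-hour steps/day)")
print(f"unreleased drizzle buffer: {forcing.attrs['drizzle_buffer_mm']:.3f} mm")
```

```
                      tair  precip  relhum  surf_pressure    co2
2053-01-01 00:00:00  1.019     0.0  83.093     100536.897  534.0
2053-01-01 00:30:00  0.829     0.0  83.931     100521.965  534.0
2053-01-01 01:00:00  0.639     0.0  84.777     100507.034  534.0
2053-01-01 01:30:00  0.449     0.0  85.633     100492.102  534.0
rows: 87648 (5 years x 48 half-hour steps/day)
unreleased drizzle buffer: 0.886 mm
```

## Command-line interface

The `ecoforce` console script exposes the pipeline steps as subcommands:
`evaluate` (skill tables from observation and run files), `rank`,
`select`, `windows` (warming-level windows from a GMT CSV), `indices`
(climatological diagnostics/anomaly reports) and `extract` (one forcing
CSV per warming level). Run `ecoforce --help` for options.

## Reproduction

Run the full test suite (unit, property-based and acceptance tests):

```
python -m pytest -q tests/
```

One acceptance test, `test_criterion_4_crossing_year_recovery`, is an
intentionally strict tolerance check that fails for statistical reasons
documented in `docs/methods.md` (limitations section); all other tests
pass.

Produce the headline pipeline quantities as JSON (everything is derived
from `--seed`):

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `ecoforce.io_formats` — station archive (ECA&D-style), CF/NetCDF point
  extraction, GHG/GMT CSV readers, forcing-table writer.
- `ecoforce.skill_metrics` — model-vs-observation skill metrics.
- `ecoforce.climate_indices` — ETCCDI-style indices and diagnostics.
- `ecoforce.model_selection` — ranking, shortlisting, ensemble
  representativeness screen, final selection.
- `ecoforce.gmt_windows` — warming-level smoothing, threshold crossing,
  window construction, window-length sensitivity.
- `ecoforce.forcing_builder` — 3-hourly → 30-minute forcing assembly.
- `ecoforce.synthetic_weather` — seeded stochastic weather/GMT generator.
- `ecoforce.datasets` — published precipitation-bias ranking and
  index-change tables used as worked-example fixtures.
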