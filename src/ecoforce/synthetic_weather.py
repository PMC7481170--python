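"""Stochastic weather and warming-trajectory generators for pipeline testing.

The generators emulate a temperate-maritime station climatology and an
ensemble of biased pseudo-model runs: a single annual harmonic plus an
AR(1) anomaly for air temperature, a first-order two-state Markov chain
for precipitation occurrence with gamma-distributed wet-day amounts,
harmonic relative humidity and Weibull wind. Every generator is
deterministic given its seed; each variable draws from its own fixed
substream so adding one variable never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import ModelRun, validate_daily

__all__ = [
    "SyntheticClimateSpec",
    "BiasSpec",
    "GmtTrajectorySpec",
    "gen_station_obs",
    "gen_model_run",
    "gen_subdaily",
    "gen_gmt",
]


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of the synthetic station climate.

    Defaults are set to a north-west European lowland climate: ~10 degC
    annual mean with a 7.5 degC seasonal half-amplitude, day-to-day
    anomalies with lag-1 autocorrelation 0.7 and 2 degC marginal sd, an
    8 degC mean diurnal range, roughly one wet day in two with a mean
    wet-day depth near 4 mm (annual total ~750 mm), humid winters and
    Weibull-distributed wind around 4 m/s.
    """

    seed: int = 0
    n_years: int = 10
    start_year: int = 1951
    tmean_mean: float = 10.0          # degC
    tmean_amplitude: float = 7.5      # degC, seasonal half-amplitude
    ar1: float = 0.7                  # lag-1 autocorrelation of anomalies
    noise_sd: float = 2.0             # degC, marginal anomaly sd
    dtr_mean: float = 8.0             # degC
    p01: float = 0.4                  # P(wet | previous day dry)
    p11: float = 0.6                  # P(wet | previous day wet)
    gamma_shape: float = 0.8          # wet-day amount, shape
    gamma_scale: float = 5.0          # wet-day amount, scale (mm)
    relhum_mean: float = 80.0         # %
    relhum_amplitude: float = 7.0     # %, winter maximum
    wind_shape: float = 2.0           # Weibull shape
    wind_scale: float = 4.5           # Weibull scale (m/s)

    def __post_init__(self) -> None:
        for p in (self.p01, self.p11):
            if not 0.0 <= p <= 1.0:
                raise ValueError("Markov probabilities must lie in [0, 1]")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if min(self.tmean_amplitude, self.relhum_amplitude, self.dtr_mean) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")


@dataclass(frozen=True)
class BiasSpec:
    """Systematic offsets applied to a pseudo-model run relative to truth."""

    t_bias: float = 0.0               # additive, degC
    p_factor: float = 1.0             # multiplicative on precipitation
    rh_bias: float = 0.0              # additive, %
    wind_factor: float = 1.0          # multiplicative on wind
    variance_inflation: float = 1.0   # on temperature-anomaly variance

    def __post_init__(self) -> None:
        if self.p_factor <= 0 or self.wind_factor <= 0 or self.variance_inflation <= 0:
            raise ValueError("multiplicative factors must be positive")


@dataclass(frozen=True)
class GmtTrajectorySpec:
    """An annual global-mean-temperature trajectory: baseline + trend + noise."""

    start_year: int = 1921
    n_years: int = 180
    baseline: float = 13.8            # degC
    trend: float = 0.02               # degC/yr (scalar, applied from start)
    noise_sd: float = 0.0             # degC, interannual
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")


# Fixed substream positions: one per variable, never reordered.
_STREAMS = {"tanom": 0, "trange": 1, "pocc": 2, "pamt": 3, "relhum": 4, "wind": 5}


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(children[i]) for name, i in _STREAMS.items()}


def _doy_fraction(index: pd.DatetimeIndex) -> np.ndarray:
    return (index.dayofyear.to_numpy() - 15) / 365.25


def gen_station_obs(spec: SyntheticClimateSpec) -> pd.DataFrame:
    """Generate a daily observation series for one synthetic station."""
    rng = _rngs(spec.seed)
    index = pd.date_range(
        f"{spec.start_year}-01-01",
        f"{spec.start_year + spec.n_years - 1}-12-31",
        freq="D",
    )
    n = len(index)
    phase = 2 * np.pi * _doy_fraction(index)

    # temperature: annual harmonic (minimum mid-January) + AR(1) anomaly
    clim = spec.tmean_mean - spec.tmean_amplitude * np.cos(phase)
    eps_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar1**2)
    eps = rng["tanom"].normal(0.0, eps_sd, n)
    anom = np.empty(n)
    prev = rng["tanom"].normal(0.0, spec.noise_sd)
    for i in range(n):
        prev = spec.ar1 * prev + eps[i]
        anom[i] = prev
    tmean = clim + anom

    half = spec.dtr_mean / 2.0
    jitter = rng["trange"].normal(0.0, 0.5, (2, n))
    tmin = np.minimum(tmean - half + jitter[0], tmean)
    tmax = np.maximum(tmean + half + jitter[1], tmean)

    # precipitation: 2-state Markov occurrence, gamma amounts on wet days
    occ_u = rng["pocc"].random(n)
    wet = np.zeros(n, dtype=bool)
    prev_wet = False
    for i in range(n):
        p = spec.p11 if prev_wet else spec.p01
        prev_wet = occ_u[i] < p
        wet[i] = prev_wet
    amounts = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        amounts[wet] = rng["pamt"].gamma(spec.gamma_shape, spec.gamma_scale, n_wet)

    relhum = np.clip(
        spec.relhum_mean
        + spec.relhum_amplitude * np.cos(phase)
        + rng["relhum"].normal(0.0, 4.0, n),
        0.0, 100.0,
    )
    wind = spec.wind_scale * rng["wind"].weibull(spec.wind_shape, n)

    frame = pd.DataFrame(
        {"tmean": tmean, "tmin": tmin, "tmax": tmax,
         "precip": amounts, "relhum": relhum, "wind": wind},
        index=index,
    )
    return validate_daily(frame, name="synthetic obs")


def gen_model_run(
    obs_spec: SyntheticClimateSpec,
    bias: BiasSpec,
    seed: int,
    experiment: str = "historical",
    *,
    rcm_name: str = "SYNRCM",
    gcm_name: str = "SYNGCM",
    trend: float = 0.0,
    calendar: str = "standard",
) -> ModelRun:
    """Generate a pseudo-model run: an independent draw plus known biases.

    ``trend`` adds a linear warming (degC/yr, from the first series year)
    to all temperatures, for scenario-style runs. Long-run mean offsets
    from a same-spec observation draw equal the bias spec up to sampling
    error.
    """
    draw_spec = replace(
        obs_spec,
        seed=seed,
        noise_sd=obs_spec.noise_sd * np.sqrt(bias.variance_inflation),
    )
    daily = gen_station_obs(draw_spec)
    years_in = (daily.index - daily.index[0]).days / 365.25
    warming = trend * years_in.to_numpy()
    for col in ("tmean", "tmin", "tmax"):
        daily[col] = daily[col] + bias.t_bias + warming
    daily["precip"] = daily["precip"] * bias.p_factor
    daily["relhum"] = np.clip(daily["relhum"] + bias.rh_bias, 0.0, 100.0)
    daily["wind"] = daily["wind"] * bias.wind_factor
    if experiment == "evaluation":
        gcm_name = "reanalysis"
    return ModelRun(
        rcm_name=rcm_name,
        gcm_name=gcm_name,
        experiment=experiment,
        daily=daily,
        calendar=calendar,
    )


def gen_subdaily(daily: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Expand a daily series to 3-hourly steps (8 per day).

    Temperature follows a diurnal harmonic centred on (tmin+tmax)/2 with
    its maximum at 15 h, so all steps stay inside [tmin, tmax]; each
    day's step precipitation sums exactly to the daily total; sea-level
    pressure is a smooth synthetic series; specific humidity is derived
    from the daily relative humidity so the humidity conversion can be
    exercised end to end. Heat-flux columns are included at native
    resolution.
    """
    required = {"tmean", "tmin", "tmax", "precip"}
    if not required <= set(daily.columns) or daily[sorted(required)].isna().any().any():
        raise ValueError("gen_subdaily requires complete tmean/tmin/tmax/precip")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))

    n_days = len(daily)
    hours = np.arange(0, 24, 3)
    index = pd.DatetimeIndex(
        np.repeat(daily.index.to_numpy(), 8)
        + np.tile(hours, n_days) * np.timedelta64(1, "h")
    )

    center = (daily["tmin"].to_numpy() + daily["tmax"].to_numpy()) / 2.0
    amp = (daily["tmax"].to_numpy() - daily["tmin"].to_numpy()) / 2.0
    harm = np.cos(2 * np.pi * (hours - 15) / 24.0)
    tair = (center[:, None] + amp[:, None] * harm[None, :]).ravel()

    totals = daily["precip"].to_numpy()
    weights = rng.gamma(0.3, 1.0, (n_days, 8))
    wsum = weights.sum(axis=1, keepdims=True)
    wsum[wsum <= 0] = 1.0
    precip = (totals[:, None] * weights / wsum).ravel()

    # mean-reverting synoptic pressure: stationary AR(1) around the
    # standard atmosphere, stationary sd ~750 Pa regardless of length
    phi = 0.98
    shocks = rng.normal(0.0, 150.0, n_days)
    mslp_daily = np.empty(n_days)
    state = 0.0
    for i in range(n_days):
        state = phi * state + shocks[i]
        mslp_daily[i] = 101325.0 + state
    mslp = np.repeat(mslp_daily, 8) + rng.normal(0.0, 30.0, n_days * 8)

    rh_daily = daily["relhum"].to_numpy() if "relhum" in daily else np.full(n_days, 70.0)
    rh = np.clip(np.repeat(rh_daily, 8) + rng.normal(0.0, 2.0, n_days * 8), 1.0, 100.0)
    # invert the Magnus relation used downstream, so conversion roundtrips
    es = 611.2 * np.exp(17.62 * tair / (243.12 + tair))
    e = rh / 100.0 * es
    eps = 0.622
    spechum = eps * e / (mslp - (1.0 - eps) * e)

    wind_daily = daily["wind"].to_numpy() if "wind" in daily else np.full(n_days, 4.0)
    wind = np.maximum(np.repeat(wind_daily, 8) + rng.normal(0.0, 0.5, n_days * 8), 0.0)

    lhflux = np.maximum(rng.normal(60.0, 25.0, n_days * 8), 0.0)
    shflux = rng.normal(30.0, 20.0, n_days * 8)

    return pd.DataFrame(
        {"tmean": tair, "precip": precip, "mslp": mslp, "spechum": spechum,
         "wind": wind, "lhflux": lhflux, "shflux": shflux},
        index=index,
    )


def gen_gmt(spec: GmtTrajectorySpec) -> pd.Series:
    """Generate an annual GMT series: baseline + trend*(year-start) + noise."""
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    values = spec.baseline + spec.trend * (years - spec.start_year)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(202,)))
        values = values + rng.normal(0.0, spec.noise_sd, spec.n_years)
    return pd.Series(values, index=pd.Index(years, name="year"), name="gmt")
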