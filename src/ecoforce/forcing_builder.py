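"""Turn 3-hourly model output into 30-min chamber forcing tables.

State variables (air temperature, pressure, humidity, wind) are
linearly interpolated from the 3-hourly knots to 30-min steps.
Precipitation is never interpolated — interpolating accumulations would
destroy mass conservation — but split uniformly over each knot's six
sub-steps and then passed through the drizzle filter: amounts below
1 mm are postponed and accumulated until the buffer reaches 1 mm, so
every precipitation event the facility's irrigation hardware is asked
to deliver is at least 1 mm deep. Surface pressure is reduced from mean
sea level with the isothermal hydrostatic formula at the facility
elevation; specific humidity is converted to relative humidity with the
Magnus saturation formula (over water). Annual greenhouse-gas
concentrations are attached as step functions of the year.

Latent and sensible heat fluxes are deliberately not interpolated and
stay at their native 3-h resolution on the source run.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import GhgTable, ModelRun, WarmingWindow

__all__ = [
    "interpolate_linear",
    "disaggregate_precip",
    "drizzle_filter",
    "surface_pressure_from_msl",
    "relative_humidity_from_specific",
    "specific_humidity_from_relative",
    "assemble_forcing",
]

logger = logging.getLogger(__name__)

GRAVITY = 9.80665        # m/s2
R_DRY = 287.05           # J/(kg K)
EPSILON = 0.622          # ratio of molar masses, water vapour / dry air
ECOTRON_ELEVATION = 43.0  # m a.s.l.

#: Sub-daily columns that are linearly interpolated (when present).
STATE_VARIABLES = ("tmean", "mslp", "surf_pressure", "spechum", "relhum", "wind")


def _step_of(index: pd.DatetimeIndex) -> pd.Timedelta:
    steps = np.unique(np.diff(index.to_numpy()))
    if len(steps) != 1:
        raise ValueError("irregular time step")
    return pd.Timedelta(steps[0])


def interpolate_linear(series: pd.DataFrame | pd.Series, target: str = "30min"):
    """Linear interpolation of state variables onto a finer regular grid.

    Original knots are preserved exactly; values between knots lie on
    the straight line. Applies to temperature, pressure, humidity and
    wind — not to precipitation or heat fluxes.
    """
    frame = series.to_frame() if isinstance(series, pd.Series) else series
    _step_of(frame.index)
    new_index = pd.date_range(frame.index[0], frame.index[-1], freq=target)
    x_old = (frame.index - frame.index[0]).total_seconds().to_numpy()
    x_new = (new_index - frame.index[0]).total_seconds().to_numpy()
    out = pd.DataFrame(
        {col: np.interp(x_new, x_old, frame[col].to_numpy()) for col in frame.columns},
        index=new_index,
    )
    return out[series.name] if isinstance(series, pd.Series) else out


def disaggregate_precip(precip: pd.Series, target: str = "30min") -> pd.Series:
    """Split each accumulation uniformly over its sub-steps, conserving mass.

    A 3-h amount v becomes six 30-min amounts; the last sub-step takes
    the remainder v - 5*(v/6) so the per-knot sum is exact.
    """
    values = precip.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative precipitation input")
    step = _step_of(precip.index)
    sub = pd.Timedelta(target)
    n_sub, remainder = divmod(step, sub)
    if remainder != pd.Timedelta(0):
        raise ValueError(f"target step {target} does not divide input step {step}")
    n_sub = int(n_sub)
    even = values / n_sub
    chunks = np.repeat(even, n_sub).reshape(-1, n_sub)
    chunks[:, -1] = values - (n_sub - 1) * even
    index = pd.DatetimeIndex(
        np.repeat(precip.index.to_numpy(), n_sub)
        + np.tile(np.arange(n_sub), len(precip)) * sub.to_timedelta64()
    )
    return pd.Series(chunks.ravel(), index=index, name=precip.name)


def drizzle_filter(
    precip: np.ndarray | pd.Series, threshold: float = 1.0
) -> tuple[np.ndarray, float]:
    """Postpone sub-threshold precipitation until it accumulates to an event.

    Scanning in time order: while the running buffer plus the step
    amount stays below the threshold, the step outputs 0 and the amount
    joins the buffer; once the accumulated total attains the threshold
    it is released in full at that step and the buffer resets. Returns
    the filtered amounts and the terminal buffer (never silently
    dropped). Every released event is at least ``threshold`` deep.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = np.asarray(precip, dtype=float)
    if (values < 0).any():
        raise ValueError("negative precipitation input")
    out = np.zeros_like(values)
    pending: list[float] = []
    for i, amount in enumerate(values):
        pending.append(amount)
        total = math.fsum(pending)
        if total >= threshold:
            out[i] = total
            pending.clear()
    return out, math.fsum(pending)


def surface_pressure_from_msl(mslp, tair, elevation: float = ECOTRON_ELEVATION):
    """Isothermal hydrostatic reduction of mean-sea-level pressure to a site.

    p = mslp * exp(-g z / (R_d T_K)) with the concurrent air temperature
    in kelvin; at elevation 0 this is the identity.
    """
    mslp = np.asarray(mslp, dtype=float)
    if (mslp <= 0).any():
        raise ValueError("non-positive mean sea level pressure")
    t_kelvin = np.asarray(tair, dtype=float) + 273.15
    return mslp * np.exp(-GRAVITY * elevation / (R_DRY * t_kelvin))


def _saturation_vapor_pressure(tair):
    """Magnus formula over water, Pa; tair in degC."""
    tair = np.asarray(tair, dtype=float)
    return 611.2 * np.exp(17.62 * tair / (243.12 + tair))


def relative_humidity_from_specific(spechum, tair, pressure):
    """Specific humidity (kg/kg) to relative humidity (%), clipped to [0, 100].

    Vapour pressure e = q p / (eps + (1-eps) q); RH = 100 e / e_s(T)
    with the Magnus saturation formula over water. Supersaturated
    inputs are clipped to 100 % and the clipping is logged.
    """
    q = np.asarray(spechum, dtype=float)
    if (q < 0).any():
        raise ValueError("negative specific humidity")
    e = q * np.asarray(pressure, dtype=float) / (EPSILON + (1.0 - EPSILON) * q)
    rh = 100.0 * e / _saturation_vapor_pressure(tair)
    n_clipped = int(np.sum((rh < 0) | (rh > 100)))
    if n_clipped:
        logger.info("clipped %d supersaturated/negative RH value(s)", n_clipped)
    return np.clip(rh, 0.0, 100.0)


def specific_humidity_from_relative(relhum, tair, pressure):
    """Inverse of :func:`relative_humidity_from_specific` (kg/kg)."""
    e = np.asarray(relhum, dtype=float) / 100.0 * _saturation_vapor_pressure(tair)
    return EPSILON * e / (np.asarray(pressure, dtype=float) - (1.0 - EPSILON) * e)


def assemble_forcing(
    run: ModelRun,
    windows: list[WarmingWindow],
    ghg: GhgTable,
    elevation: float = ECOTRON_ELEVATION,
    drizzle_threshold: float = 1.0,
) -> dict[float, pd.DataFrame]:
    """Build one 30-min forcing table per warming-level window.

    Per window: slice the run's 3-hourly series, interpolate the state
    variables, disaggregate and drizzle-filter precipitation, derive
    surface pressure from mean sea level pressure and relative humidity
    from specific humidity where not directly available, and attach the
    annual greenhouse-gas concentrations stepwise-constant per year.
    Precipitation is emitted both as event depth per 30-min step
    (``precip``) and as intensity (``precip_intensity``, mm/h); the
    terminal drizzle buffer is recorded in ``attrs['drizzle_buffer_mm']``.
    """
    if run.subdaily is None or run.subdaily.empty:
        raise ValueError(f"run {run.label} carries no sub-daily data")
    if "tmean" not in run.subdaily.columns or "precip" not in run.subdaily.columns:
        raise ValueError("sub-daily data must include at least tmean and precip")

    sub = run.subdaily
    tables: dict[float, pd.DataFrame] = {}
    for window in windows:
        years = np.asarray(sub.index.year)
        sliced = sub[(years >= window.start_year) & (years <= window.end_year)]
        if sliced.empty or sliced.index[0].year > window.start_year \
                or sliced.index[-1].year < window.end_year:
            raise ValueError(
                f"window {window.start_year}-{window.end_year} "
                f"(threshold {window.threshold}) outside sub-daily coverage"
            )
        missing = [y for y in window.years if y not in ghg.years]
        if missing:
            raise ValueError(f"GHG table does not cover year(s) {missing}")

        state_cols = [c for c in STATE_VARIABLES if c in sliced.columns]
        state = interpolate_linear(sliced[state_cols])
        # extend the tail beyond the last knot to complete the final day
        step = pd.Timedelta("30min")
        full_index = pd.date_range(sliced.index[0],
                                   sliced.index[-1].normalize()
                                   + pd.Timedelta("23:30:00"), freq=step)
        state = state.reindex(full_index).ffill()

        sub_precip = disaggregate_precip(sliced["precip"]).reindex(full_index,
                                                                   fill_value=0.0)
        released, buffer_mm = drizzle_filter(sub_precip.to_numpy(), drizzle_threshold)

        tair = state["tmean"].to_numpy()
        if "surf_pressure" in state:
            pressure = state["surf_pressure"].to_numpy()
        elif "mslp" in state:
            pressure = surface_pressure_from_msl(state["mslp"].to_numpy(),
                                                 tair, elevation)
        else:
            raise ValueError("need surf_pressure or mslp to build forcing")
        if "relhum" in state:
            relhum = state["relhum"].to_numpy()
        elif "spechum" in state:
            relhum = relative_humidity_from_specific(state["spechum"].to_numpy(),
                                                     tair, pressure)
        else:
            raise ValueError("need relhum or spechum to build forcing")

        table = pd.DataFrame(
            {
                "tair": tair,
                "precip": released,
                "precip_intensity": released / (step / pd.Timedelta("1h")),
                "relhum": relhum,
                "wind": state["wind"].to_numpy() if "wind" in state else np.nan,
                "surf_pressure": pressure,
            },
            index=full_index,
        )
        ghg_rows = ghg.table.loc[full_index.year]
        for gas in ("co2", "ch4", "n2o"):
            table[gas] = ghg_rows[gas].to_numpy()

        table.attrs["run"] = run.label
        table.attrs["window"] = (window.start_year, window.end_year)
        table.attrs["threshold"] = window.threshold
        table.attrs["drizzle_buffer_mm"] = buffer_mm
        tables[window.threshold] = table
    return tables
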