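"""Core in-memory containers shared across the pipeline.

Daily meteorology travels as a plain :class:`pandas.DataFrame` with a
date index and a fixed column vocabulary; the dataclasses here carry the
metadata (station coordinates, model/run identity, calendar, warming
window bounds) that a bare frame cannot.

Internal units are fixed everywhere: air temperature in degC,
precipitation in mm per accumulation step, relative humidity in %,
wind speed in m/s, pressure in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised daily-variable column names, in canonical order.
DAILY_VARIABLES = ("tmean", "tmin", "tmax", "precip", "relhum", "wind")

#: Recognised sub-daily (3-hourly input / 30-min output) column names.
SUBDAILY_VARIABLES = (
    "tmean", "precip", "mslp", "surf_pressure", "spechum", "relhum",
    "wind", "lhflux", "shflux",
)

CALENDARS = ("standard", "365_day", "360_day")

EXPERIMENTS = ("evaluation", "historical", "rcp85")


class DataIntegrityError(ValueError):
    """A physical-consistency invariant of the data is violated."""


def validate_daily(df: pd.DataFrame, *, name: str = "series") -> pd.DataFrame:
    """Validate a daily meteorology frame against the shared invariants.

    Checks strictly increasing unique dates, known columns, precip >= 0,
    relhum in [0, 100], wind >= 0 and tmin <= tmean <= tmax wherever all
    three are present. Returns the frame unchanged on success.
    """
    unknown = set(df.columns) - set(DAILY_VARIABLES)
    if unknown:
        raise DataIntegrityError(f"{name}: unknown columns {sorted(unknown)}")
    if df.index.has_duplicates:
        raise DataIntegrityError(f"{name}: duplicate dates in index")
    if not df.index.is_monotonic_increasing:
        raise DataIntegrityError(f"{name}: dates not increasing")
    if "precip" in df and (df["precip"].dropna() < 0).any():
        raise DataIntegrityError(f"{name}: negative precipitation")
    if "relhum" in df:
        rh = df["relhum"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise DataIntegrityError(f"{name}: relative humidity outside [0, 100]")
    if "wind" in df and (df["wind"].dropna() < 0).any():
        raise DataIntegrityError(f"{name}: negative wind speed")
    if {"tmin", "tmean", "tmax"} <= set(df.columns):
        sub = df[["tmin", "tmean", "tmax"]].dropna()
        bad = (sub["tmin"] > sub["tmean"]) | (sub["tmean"] > sub["tmax"])
        if bad.any():
            raise DataIntegrityError(
                f"{name}: tmin <= tmean <= tmax violated on {int(bad.sum())} day(s)"
            )
    return df


@dataclass
class StationRecord:
    """A weather station with its daily observation series."""

    station_id: str
    name: str
    lon: float
    lat: float
    elevation: float
    series: pd.DataFrame

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")
        validate_daily(self.series, name=f"station {self.station_id}")


@dataclass
class ModelRun:
    """One climate-model simulation: identity, calendar and its series.

    ``gcm_name`` is ``"reanalysis"`` for evaluation (reanalysis-driven)
    runs. The calendar is declared metadata, never guessed: readers
    refuse files without one.
    """

    rcm_name: str
    gcm_name: str
    experiment: str
    daily: pd.DataFrame
    member: str = "r1i1p1"
    calendar: str = "standard"
    subdaily: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.calendar not in CALENDARS:
            raise ValueError(f"unknown calendar {self.calendar!r}")
        if self.experiment == "evaluation" and self.gcm_name != "reanalysis":
            raise ValueError("evaluation runs must declare gcm_name='reanalysis'")
        validate_daily(self.daily, name=self.label)

    @property
    def label(self) -> str:
        return f"{self.rcm_name}/{self.gcm_name}"


@dataclass(frozen=True)
class WarmingWindow:
    """An extraction window tied to a global warming threshold."""

    threshold: float
    crossing_year: int
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")
        if not self.start_year <= self.crossing_year <= self.end_year:
            raise ValueError("crossing year outside window")

    @property
    def length(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


@dataclass
class GhgTable:
    """Annual greenhouse-gas concentrations (CO2 ppm, CH4 ppb, N2O ppb)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"co2", "ch4", "n2o"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GHG table missing columns {sorted(missing)}")
        years = self.table.index.to_numpy()
        if len(years) == 0:
            raise ValueError("empty GHG table")
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError("GHG table years must be contiguous")
        if (self.table[sorted(required)] <= 0).any().any():
            raise ValueError("GHG concentrations must be positive")

    def lookup(self, year: int) -> pd.Series:
        if year not in self.table.index:
            raise KeyError(
                f"year {year} outside GHG table range "
                f"{self.table.index[0]}-{self.table.index[-1]}"
            )
        return self.table.loc[year]

    @property
    def years(self) -> pd.Index:
        return self.table.index
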