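"""Climatological diagnostics and ETCCDI-style climate extremes indices.

Used twice in the pipeline: to evaluate model runs against station
observations (diurnal temperature range, wet/frost days, Rx1day,
dry/wet spell lengths) and to characterise the extracted warming-level
windows relative to a reference period (mean temperature, TXx, TNn,
frost and summer days, growing season length, PRCPTOT, Rx1day, R10mm,
CDD, CWD).

Annual quantities are computed per calendar year (spells truncate at
year boundaries) and summarised as the mean over years; Rx1day is the
mean over monthly 1-day maxima by default. Day-count thresholds follow
the ETCCDI conventions: wet day P > 0.1 mm or P > 1 mm, frost day
Tmin < 0 degC, summer day Tmax > 25 degC, heavy precipitation day
P > 10 mm, dry day P < 1 mm, wet-spell day P >= 1 mm.
"""

from __future__ import annotations

import datetime
import operator

import numpy as np
import pandas as pd

from .containers import DataIntegrityError

__all__ = [
    "diurnal_temperature_range",
    "count_days",
    "frost_days",
    "summer_days",
    "wet_days",
    "r10mm",
    "rx1day",
    "rx1day_monthly",
    "max_spell",
    "growing_season_length",
    "prcptot",
    "txx_tnn",
    "climatological_diagnostics",
    "table_indices",
    "index_anomaly_report",
    "days_not_favorable_for_growth",
    "DIAGNOSTIC_NAMES",
    "TABLE_INDEX_NAMES",
]

_COMPARATORS = {">": operator.gt, "<": operator.lt, ">=": operator.ge, "<=": operator.le}


def _years(index) -> np.ndarray:
    return np.asarray(index.year)


def _assert_whole_years(series: pd.Series, *, allow_partial: bool = False) -> None:
    """Require a gap-free series of complete calendar years (any calendar)."""
    if series.isna().any():
        raise DataIntegrityError("missing values in daily series")
    if allow_partial:
        return
    idx = series.index
    one_day = (datetime.timedelta(days=1)
               if not isinstance(idx, pd.DatetimeIndex) else pd.Timedelta(days=1))
    first, last = idx[0], idx[-1]
    if not (first.month == 1 and first.day == 1):
        raise DataIntegrityError(f"series starts mid-year at {first}")
    after = last + one_day
    if not (after.month == 1 and after.day == 1):
        raise DataIntegrityError(f"series ends mid-year at {last}")
    # gap-free: total days equals index length
    span = (after - first)
    n_days = span.days if hasattr(span, "days") else int(span / pd.Timedelta(days=1))
    if n_days != len(idx):
        raise DataIntegrityError("gaps in daily series")


def _season_mask(index, season: str) -> np.ndarray:
    months = np.asarray(index.month)
    if season == "annual":
        return np.ones(len(months), dtype=bool)
    if season == "DJF":
        mask = np.isin(months, (12, 1, 2))
        mask &= ~((months == 12) & (_years(index) == _years(index).max()))
        return mask
    if season == "JJA":
        return np.isin(months, (6, 7, 8))
    raise ValueError(f"unknown season {season!r}")


def diurnal_temperature_range(
    tmax: pd.Series, tmin: pd.Series, season: str = "annual"
) -> float:
    """Mean daily (tmax - tmin) over the selected season, in degC."""
    frame = pd.concat({"tmax": tmax, "tmin": tmin}, axis=1).dropna()
    spread = frame["tmax"] - frame["tmin"]
    if (spread < 0).any():
        raise DataIntegrityError("tmax < tmin on some day(s)")
    return float(spread[_season_mask(frame.index, season)].mean())


def count_days(
    series: pd.Series,
    comparator: str,
    threshold: float,
    *,
    allow_partial: bool = False,
) -> pd.Series:
    """Days per calendar year satisfying ``value <comparator> threshold``.

    The comparison is strict exactly as configured (e.g. P > 0.1 mm,
    Tmin < 0 degC). Returns the per-year counts; the period value is
    their mean.
    """
    _assert_whole_years(series, allow_partial=allow_partial)
    hit = pd.Series(
        _COMPARATORS[comparator](series.to_numpy(), threshold), index=series.index
    )
    return hit.groupby(_years(hit.index)).sum().astype(float)


def frost_days(tmin: pd.Series, *, on: str = "tmin", **kw) -> pd.Series:
    """Days with minimum (default) or mean air temperature below 0 degC."""
    if on not in ("tmin", "tmean"):
        raise ValueError("frost days are defined on tmin or tmean")
    return count_days(tmin, "<", 0.0, **kw)


def summer_days(tmax: pd.Series, **kw) -> pd.Series:
    return count_days(tmax, ">", 25.0, **kw)


def wet_days(precip: pd.Series, threshold: float = 0.1, **kw) -> pd.Series:
    return count_days(precip, ">", threshold, **kw)


def r10mm(precip: pd.Series, **kw) -> pd.Series:
    return count_days(precip, ">", 10.0, **kw)


def rx1day_monthly(precip: pd.Series) -> pd.Series:
    """Maximum 1-day precipitation within each calendar month (mm/day)."""
    if precip.isna().any():
        raise DataIntegrityError("missing values in precipitation series")
    years, months = _years(precip.index), np.asarray(precip.index.month)
    return precip.groupby([years, months]).max()


def rx1day(precip: pd.Series, aggregate: str = "mean") -> float:
    """Period Rx1day: mean (default) or overall max of the monthly maxima."""
    monthly = rx1day_monthly(precip)
    if aggregate == "mean":
        return float(monthly.mean())
    if aggregate == "max":
        return float(monthly.max())
    raise ValueError("aggregate must be 'mean' or 'max'")


def _longest_run(flags: np.ndarray) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def max_spell(precip: pd.Series, kind: str, **kw) -> pd.Series:
    """Longest annual dry (P < 1 mm) or wet (P >= 1 mm) spell, per year.

    Runs truncate at calendar-year boundaries; the period value is the
    mean of the annual maxima.
    """
    if (precip.dropna() < 0).any():
        raise DataIntegrityError("negative precipitation")
    _assert_whole_years(precip, **kw)
    if kind == "dry":
        flags = precip.to_numpy() < 1.0
    elif kind == "wet":
        flags = precip.to_numpy() >= 1.0
    else:
        raise ValueError("kind must be 'dry' or 'wet'")
    groups = pd.Series(flags, index=precip.index).groupby(_years(precip.index))
    return groups.apply(lambda s: float(_longest_run(s.to_numpy())))


def _first_span(flags: np.ndarray, span: int, start: int = 0) -> int | None:
    """Index of the first run of ``span`` consecutive True values at/after start."""
    run = 0
    for i in range(start, len(flags)):
        run = run + 1 if flags[i] else 0
        if run == span:
            return i - span + 1
    return None


def growing_season_length(tmean: pd.Series, span: int = 6, **kw) -> pd.Series:
    """Growing season length per calendar year, in days.

    Counted from the first day of the first span of at least ``span``
    days with mean air temperature above 5 degC to the day before the
    first span, starting after July 1, of ``span`` days below 5 degC.
    No warm span gives 0; no qualifying cold span ends the season at
    the last day of the year.
    """
    _assert_whole_years(tmean, **kw)
    out = {}
    for year, values in tmean.groupby(_years(tmean.index)):
        t = values.to_numpy()
        warm_start = _first_span(t > 5.0, span)
        if warm_start is None:
            out[year] = 0.0
            continue
        months = np.asarray(values.index.month)
        july1 = int(np.argmax(months == 7))
        cold_start = _first_span(t < 5.0, span, start=max(july1, warm_start))
        end = len(t) if cold_start is None else cold_start
        out[year] = float(max(end - warm_start, 0))
    return pd.Series(out)


def prcptot(precip: pd.Series, **kw) -> pd.Series:
    """Annual accumulated precipitation (mm/year), per year."""
    if (precip.dropna() < 0).any():
        raise DataIntegrityError("negative precipitation")
    _assert_whole_years(precip, **kw)
    return precip.groupby(_years(precip.index)).sum()


def txx_tnn(tmax: pd.Series, tmin: pd.Series, **kw) -> tuple[pd.Series, pd.Series]:
    """Per-year TXx (annual max of tmax) and TNn (annual min of tmin)."""
    _assert_whole_years(tmax, **kw)
    _assert_whole_years(tmin, **kw)
    return (
        tmax.groupby(_years(tmax.index)).max(),
        tmin.groupby(_years(tmin.index)).min(),
    )


DIAGNOSTIC_NAMES = (
    "DTR", "DTR_DJF", "DTR_JJA", "wet_days_0.1", "wet_days_1",
    "frost_days", "Rx1day", "CDD", "CWD",
)


def climatological_diagnostics(daily: pd.DataFrame, **kw) -> dict[str, float]:
    """The evaluation diagnostics, as period values, for one daily series."""
    out: dict[str, float] = {}
    if {"tmax", "tmin"} <= set(daily.columns):
        for season, name in (("annual", "DTR"), ("DJF", "DTR_DJF"), ("JJA", "DTR_JJA")):
            out[name] = diurnal_temperature_range(daily["tmax"], daily["tmin"], season)
        out["frost_days"] = float(frost_days(daily["tmin"], **kw).mean())
    if "precip" in daily.columns:
        p = daily["precip"]
        out["wet_days_0.1"] = float(wet_days(p, 0.1, **kw).mean())
        out["wet_days_1"] = float(wet_days(p, 1.0, **kw).mean())
        out["Rx1day"] = rx1day(p)
        out["CDD"] = float(max_spell(p, "dry", **kw).mean())
        out["CWD"] = float(max_spell(p, "wet", **kw).mean())
    return out


TABLE_INDEX_NAMES = (
    "T", "TXx", "TNn", "frost_days", "summer_days", "GSL",
    "PRCPTOT", "Rx1day", "R10mm", "CDD", "CWD",
)


def table_indices(daily: pd.DataFrame, **kw) -> dict[str, float]:
    """The warming-window characterisation indices, as period values."""
    txx, tnn = txx_tnn(daily["tmax"], daily["tmin"], **kw)
    return {
        "T": float(daily["tmean"].mean()),
        "TXx": float(txx.mean()),
        "TNn": float(tnn.mean()),
        "frost_days": float(frost_days(daily["tmin"], **kw).mean()),
        "summer_days": float(summer_days(daily["tmax"], **kw).mean()),
        "GSL": float(growing_season_length(daily["tmean"], **kw).mean()),
        "PRCPTOT": float(prcptot(daily["precip"], **kw).mean()),
        "Rx1day": rx1day(daily["precip"]),
        "R10mm": float(r10mm(daily["precip"], **kw).mean()),
        "CDD": float(max_spell(daily["precip"], "dry", **kw).mean()),
        "CWD": float(max_spell(daily["precip"], "wet", **kw).mean()),
    }


def index_anomaly_report(
    window: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Index changes of a window relative to the reference period.

    Returns a frame indexed by index name with columns ``reference``
    (absolute value over the reference period) and ``delta``
    (window minus reference).
    """
    ref = table_indices(reference)
    win = table_indices(window)
    return pd.DataFrame(
        {"reference": pd.Series(ref), "delta": pd.Series(win) - pd.Series(ref)}
    ).loc[list(TABLE_INDEX_NAMES)]


def days_not_favorable_for_growth(gsl_days: float, year_length: float = 365.0) -> float:
    """Days of the year outside the growing season."""
    return year_length - gsl_days
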