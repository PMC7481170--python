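"""Global-warming-level time sampling.

Annual global-mean-temperature (GMT) series are smoothed to 30-year
climatological anomalies relative to a reference period; the first year
the smoothed anomaly attains a warming threshold defines the centre of
an experiment-length extraction window. The 0 degC (historical) window
is the reference period itself.

The smoothing is a centred running mean; with an even window the extra
year goes toward the past (a 30-year window at year y covers
y-15 .. y+14), which for a linear trend a makes the anomaly exactly
a*(y - midpoint(reference) - 0.5). Years without a complete smoothing
window are dropped, never padded. Crossing uses attainment (>=), not
interpolation between years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import climate_indices
from .containers import WarmingWindow

__all__ = [
    "GmtAnomalySeries",
    "ThresholdNotReachedError",
    "WindowNotCoveredError",
    "gmt_anomaly",
    "first_crossing_year",
    "window_for_threshold",
    "windows_for_thresholds",
    "window_length_sensitivity",
]

DEFAULT_REFERENCE = (1951, 1955)
DEFAULT_THRESHOLDS = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0)


class ThresholdNotReachedError(ValueError):
    """The smoothed GMT anomaly never attains the requested threshold."""


class WindowNotCoveredError(ValueError):
    """An extraction window extends beyond the available data years."""


@dataclass
class GmtAnomalySeries:
    """Smoothed GMT anomalies with their reference period and window length."""

    series: pd.Series
    reference: tuple[int, int]
    window: int

    @property
    def reference_midpoint(self) -> int:
        return (self.reference[0] + self.reference[1]) // 2


def gmt_anomaly(
    gmt: pd.Series,
    reference: tuple[int, int] = DEFAULT_REFERENCE,
    window: int = 30,
    align: str = "centered",
) -> GmtAnomalySeries:
    """Climatological GMT anomaly: running mean minus reference-period mean.

    ``align='centered'`` (default) centres the running window on each
    year, an even remainder going toward the past; ``align='trailing'``
    ends the window at each year. Years whose smoothing window is not
    fully covered by the series are omitted.
    """
    if window < 1:
        raise ValueError("window must be at least 1")
    years = gmt.index.to_numpy()
    ref_mask = (years >= reference[0]) & (years <= reference[1])
    if ref_mask.sum() != reference[1] - reference[0] + 1:
        raise ValueError(f"reference period {reference} not fully inside series")
    ref_mean = float(gmt.to_numpy()[ref_mask].mean())

    if align == "centered":
        past, future = window // 2, (window - 1) // 2
    elif align == "trailing":
        past, future = window - 1, 0
    else:
        raise ValueError(f"unknown alignment {align!r}")

    values = gmt.to_numpy(dtype=float)
    smoothed = np.convolve(values, np.ones(window) / window, mode="valid")
    centre_years = years[past:len(years) - future]
    series = pd.Series(smoothed - ref_mean, index=pd.Index(centre_years, name="year"))
    return GmtAnomalySeries(series=series, reference=reference, window=window)


def first_crossing_year(anomalies: GmtAnomalySeries, threshold: float) -> int:
    """Smallest year whose smoothed anomaly attains the threshold.

    Threshold 0 maps by convention to the reference-period midpoint, so
    the historical window coincides with the reference period.
    """
    if threshold == 0.0:
        return anomalies.reference_midpoint
    hit = anomalies.series[anomalies.series >= threshold]
    if hit.empty:
        raise ThresholdNotReachedError(
            f"threshold {threshold} degC never attained; maximum smoothed "
            f"anomaly is {anomalies.series.max():.3f} degC"
        )
    return int(hit.index[0])


def window_for_threshold(
    crossing_year: int,
    length: int = 5,
    threshold: float = 0.0,
    available_years: tuple[int, int] | None = None,
) -> WarmingWindow:
    """Experiment-length window centred on the crossing year.

    Odd lengths are symmetric; even lengths put the extra year toward
    the past. If ``available_years`` is given, a window reaching beyond
    it raises rather than silently truncating.
    """
    if length < 1:
        raise ValueError("length must be at least 1")
    start = crossing_year - length // 2
    end = start + length - 1
    if available_years is not None and (start < available_years[0]
                                        or end > available_years[1]):
        raise WindowNotCoveredError(
            f"window {start}-{end} for threshold {threshold} exceeds available "
            f"years {available_years[0]}-{available_years[1]}"
        )
    return WarmingWindow(
        threshold=threshold, crossing_year=crossing_year,
        start_year=start, end_year=end,
    )


def windows_for_thresholds(
    anomalies: GmtAnomalySeries,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    length: int = 5,
    available_years: tuple[int, int] | None = None,
) -> list[WarmingWindow]:
    """One extraction window per warming threshold."""
    return [
        window_for_threshold(
            first_crossing_year(anomalies, t), length, t, available_years
        )
        for t in thresholds
    ]


def _slice_years(daily: pd.DataFrame, start: int, end: int) -> pd.DataFrame:
    years = np.asarray(daily.index.year)
    return daily[(years >= start) & (years <= end)]


def window_length_sensitivity(
    daily: pd.DataFrame,
    anomalies: GmtAnomalySeries,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    lengths: range = range(1, 21),
) -> pd.DataFrame:
    """Index anomalies per (window length, threshold): tidy sensitivity table.

    For each length, the reference is the 0 degC window of that same
    length; every characterisation index is recomputed over each
    threshold's window. Windows not covered by the daily series raise.
    """
    available = (int(daily.index.year.min()), int(daily.index.year.max()))
    rows = []
    for length in lengths:
        ref_window = window_for_threshold(
            anomalies.reference_midpoint, length, 0.0, available
        )
        ref_daily = _slice_years(daily, ref_window.start_year, ref_window.end_year)
        ref_idx = climate_indices.table_indices(ref_daily)
        for threshold in thresholds:
            win = window_for_threshold(
                first_crossing_year(anomalies, threshold), length, threshold, available
            )
            win_daily = _slice_years(daily, win.start_year, win.end_year)
            win_idx = climate_indices.table_indices(win_daily)
            for name in climate_indices.TABLE_INDEX_NAMES:
                rows.append({
                    "length": length, "threshold": threshold, "index": name,
                    "reference": ref_idx[name],
                    "delta": win_idx[name] - ref_idx[name],
                })
    return pd.DataFrame(rows)
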