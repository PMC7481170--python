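"""Readers and writers for every external format the pipeline touches.

Supported dialects:

* ECA&D blended daily station text (header block, then
  ``STAID, SOUID, DATE, <VAR>, Q_<VAR>`` rows, tenths-scaled values);
* CF-convention NetCDF point/grid extracts (rotated-pole aware,
  non-standard calendars carried as metadata, never coerced);
* plain CSV for GMT series, greenhouse-gas tables and 30-min forcing
  output;
* YAML run-configuration files.

After loading, everything is in the package's fixed internal units:
degC, mm per accumulation step, %, m/s, Pa.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .containers import GhgTable, validate_daily

__all__ = [
    "FormatError",
    "read_ecad_series",
    "write_ecad_series",
    "read_cf_point_series",
    "read_ghg_table",
    "write_ghg_table",
    "read_gmt_csv",
    "write_forcing_table",
    "read_forcing_table",
    "load_config",
]


class FormatError(ValueError):
    """A file does not follow its stated dialect."""


# ECA&D element codes: internal name -> (code, scale factor to physical units)
_ECAD_ELEMENTS = {
    "tmean": ("TG", 0.1),   # 0.1 degC
    "tmin": ("TN", 0.1),
    "tmax": ("TX", 0.1),
    "precip": ("RR", 0.1),  # 0.1 mm
    "relhum": ("HU", 1.0),  # 1 %
    "wind": ("FG", 0.1),    # 0.1 m/s
}


def read_ecad_series(
    path: str | Path,
    variable: str,
    *,
    drop_suspect: bool = False,
) -> pd.Series:
    """Read one variable from an ECA&D blended daily station file.

    Values are rescaled to physical units (the archive stores tenths of
    degC / mm / m/s and whole %). Rows flagged ``Q=9`` (missing) become
    NaN; rows flagged ``Q=1`` (suspect) are kept by default and dropped
    when ``drop_suspect`` is set.

    Returns a date-indexed :class:`pandas.Series` named after the
    internal variable.
    """
    if variable not in _ECAD_ELEMENTS:
        raise FormatError(
            f"unsupported variable {variable!r}; expected one of "
            f"{sorted(_ECAD_ELEMENTS)}"
        )
    code, scale = _ECAD_ELEMENTS[variable]

    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        fields = [f.strip() for f in line.split(",")]
        if "STAID" in fields and "DATE" in fields:
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(f"{path}: no 'STAID, ..., DATE, ...' column header found")

    columns = [f.strip() for f in lines[header_idx].split(",")]
    if code not in columns or f"Q_{code}" not in columns:
        raise FormatError(
            f"{path}: file carries columns {columns}, not element {code!r}"
        )

    rows = []
    for line in lines[header_idx + 1:]:
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != len(columns):
            raise FormatError(f"{path}: malformed data row {line!r}")
        rows.append(parts)
    frame = pd.DataFrame(rows, columns=columns)

    dates = pd.to_datetime(frame["DATE"], format="%Y%m%d")
    values = frame[code].astype(float) * scale
    quality = frame[f"Q_{code}"].astype(int)
    values[quality == 9] = np.nan
    if drop_suspect:
        values[quality == 1] = np.nan

    series = pd.Series(
        values.to_numpy(),
        index=pd.DatetimeIndex(dates.to_numpy(), name="date"),
        name=variable,
    )
    if series.index.has_duplicates or not series.index.is_monotonic_increasing:
        raise FormatError(f"{path}: dates not strictly increasing")
    return series


def write_ecad_series(
    series: pd.Series,
    path: str | Path,
    variable: str,
    *,
    station_id: int = 1,
    source_id: int = 1,
) -> None:
    """Write a daily series in ECA&D blended daily layout (round-trippable)."""
    if variable not in _ECAD_ELEMENTS:
        raise FormatError(f"unsupported variable {variable!r}")
    code, scale = _ECAD_ELEMENTS[variable]
    lines = [
        "EUROPEAN CLIMATE ASSESSMENT & DATASET (ECA&D) — synthetic export",
        "",
        f" STAID, SOUID,    DATE,   {code}, Q_{code}",
    ]
    for ts, value in series.items():
        if pd.isna(value):
            stored, q = -9999, 9
        else:
            stored, q = int(round(value / scale)), 0
        lines.append(
            f"{station_id:6d},{source_id:6d},{ts.strftime('%Y%m%d')},{stored:6d},{q:5d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance in km; inputs in degrees, arrays broadcast."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(h))


def read_cf_point_series(
    path: str | Path,
    variable: str,
    lon: float,
    lat: float,
) -> tuple[pd.Series, str]:
    """Extract a point series from a CF NetCDF file at the nearest grid cell.

    The cell is chosen by great-circle distance between its centre and
    ``(lon, lat)`` in true geographic coordinates, so rotated-pole grids
    (with 2-D ``lon``/``lat`` auxiliary coordinates) are handled the
    same way as regular ones. Ties go to the lowest flat cell index.

    Units are converted on the way in: kelvin to degC, precipitation
    flux (kg m-2 s-1) times the time step to mm/step. The file must
    declare its time calendar explicitly; returns ``(series, calendar)``.
    """
    raw = xr.open_dataset(path, decode_times=False)
    try:
        if "time" not in raw.variables:
            raise FormatError(f"{path}: no 'time' coordinate")
        calendar = raw["time"].attrs.get("calendar")
        if calendar is None:
            raise FormatError(f"{path}: time coordinate has no calendar attribute")
        coder = xr.coders.CFDatetimeCoder(
            use_cftime=calendar not in ("standard", "gregorian", "proleptic_gregorian")
        )
        ds = xr.decode_cf(raw, decode_times=coder)
        if variable not in ds:
            raise FormatError(f"{path}: variable {variable!r} not present")
        da = ds[variable]

        lon2d, lat2d, spatial_dims = _cell_centers(ds, da)
        if lon2d is None:  # already a point series
            point = da
        else:
            dist = _great_circle_km(lon, lat, lon2d, lat2d)
            # refuse points far outside the grid (half the max cell pitch
            # beyond the nearest centre would still be "covering"; use a
            # bounding-box test in true coordinates with a 1-degree margin)
            if not (lon2d.min() - 1 <= lon <= lon2d.max() + 1
                    and lat2d.min() - 1 <= lat <= lat2d.max() + 1):
                raise FormatError(
                    f"({lon}, {lat}) outside grid bounds "
                    f"lon [{lon2d.min():.2f}, {lon2d.max():.2f}], "
                    f"lat [{lat2d.min():.2f}, {lat2d.max():.2f}]"
                )
            flat = int(np.argmin(dist))  # argmin takes the lowest index on ties
            iy, ix = np.unravel_index(flat, dist.shape)
            point = da.isel({spatial_dims[0]: iy, spatial_dims[1]: ix})

        values = point.to_numpy().astype(float)
        units = da.attrs.get("units", "")
        if units == "K":
            values = values - 273.15
        elif units in ("kg m-2 s-1", "kg/m2/s", "kg m**-2 s**-1"):
            step = _time_step_seconds(ds)
            values = values * step  # 1 kg/m2 == 1 mm of water
        times = ds["time"].to_index()
        return pd.Series(values, index=times, name=variable), calendar
    finally:
        raw.close()


def _cell_centers(ds: xr.Dataset, da: xr.DataArray):
    """True-geographic cell-centre arrays and the spatial dims of ``da``."""
    if "lon" in ds and ds["lon"].ndim == 2:
        lon2d = ds["lon"].to_numpy()
        lat2d = ds["lat"].to_numpy()
        return lon2d, lat2d, tuple(ds["lon"].dims)
    if "lon" in ds and ds["lon"].ndim == 1 and ds["lon"].size > 0:
        if da.ndim == 1:  # point series with scalar-ish coords
            return None, None, ()
        lat1d = ds["lat"].to_numpy()
        lon1d = ds["lon"].to_numpy()
        lon2d, lat2d = np.meshgrid(lon1d, lat1d)
        return lon2d, lat2d, ("lat", "lon")
    return None, None, ()


def _time_step_seconds(ds: xr.Dataset) -> float:
    times = ds["time"].to_index()
    if len(times) < 2:
        raise FormatError("cannot infer accumulation step from a single time")
    deltas = np.diff([t for t in times])
    secs = {d.total_seconds() if hasattr(d, "total_seconds")
            else d / np.timedelta64(1, "s") for d in deltas}
    if len(secs) != 1:
        raise FormatError("irregular time step in NetCDF file")
    return float(secs.pop())


def read_ghg_table(path: str | Path) -> GhgTable:
    """Read an annual greenhouse-gas concentration CSV (year, co2, ch4, n2o)."""
    frame = pd.read_csv(path)
    required = {"year", "co2", "ch4", "n2o"}
    if not required <= set(frame.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    frame = frame.set_index("year")
    frame.index = frame.index.astype(int)
    return GhgTable(frame[["co2", "ch4", "n2o"]])


def write_ghg_table(table: GhgTable, path: str | Path) -> None:
    table.table.rename_axis("year").to_csv(path)


def read_gmt_csv(path: str | Path) -> pd.Series:
    """Read an annual global-mean-temperature CSV (year, gmt)."""
    frame = pd.read_csv(path)
    if not {"year", "gmt"} <= set(frame.columns):
        raise FormatError(f"{path}: expected columns ['year', 'gmt']")
    series = pd.Series(
        frame["gmt"].to_numpy(float),
        index=pd.Index(frame["year"].astype(int), name="year"),
        name="gmt",
    )
    if series.index.has_duplicates or not series.index.is_monotonic_increasing:
        raise FormatError(f"{path}: years not strictly increasing")
    return series


# Fixed column order of the 30-min forcing CSV.
FORCING_COLUMNS = [
    "tair", "precip", "precip_intensity", "relhum", "wind",
    "surf_pressure", "co2", "ch4", "n2o",
]


def write_forcing_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a 30-min forcing table as CSV with ISO-8601 timestamps.

    Refuses irregular time steps; the header line documents the fixed
    column order. A write/read round trip reproduces the table to 1e-9.
    """
    if len(table) > 1:
        steps = np.unique(np.diff(table.index.to_numpy()))
        if len(steps) != 1:
            raise FormatError("forcing table has an irregular time step")
    cols = [c for c in FORCING_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in FORCING_COLUMNS]
    out = table[cols + extra].copy()
    out.index.name = "timestamp"
    out.to_csv(path, float_format="%.10g", date_format="%Y-%m-%dT%H:%M:%S")


def read_forcing_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    if len(frame) > 1:
        steps = np.unique(np.diff(frame.index.to_numpy()))
        if len(steps) != 1:
            raise FormatError(f"{path}: irregular time step")
    return frame


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg
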