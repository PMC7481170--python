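"""Per-variable skill scores for evaluating model runs against observations.

Implements the evaluation battery used to rank regional-climate-model
runs at a station: mean bias, Perkins skill score (overlap of binned
empirical distributions), mean absolute error of the monthly seasonal
cycle and of the distribution tails (1st/10th/90th/99th percentiles),
RMSE, daily Spearman rank correlation, a categorical Brier skill score
against an equal-probability climatology, and the cross-variable
correlation comparison (annual / DJF / JJA).

All metrics operate on date-aligned daily series; paired-missing days
are dropped and an operation refuses to run when more than a
configurable fraction of the overlap is missing.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mean_bias",
    "perkins_skill_score",
    "seasonal_cycle",
    "seasonal_cycle_mae",
    "percentile_mae",
    "rmse",
    "spearman_daily",
    "brier_skill_score",
    "cross_correlation_table",
    "skill_table",
    "DEFAULT_BIN_WIDTHS",
    "METRIC_ORIENTATION",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25

#: Default histogram bin widths for the Perkins skill score, per variable.
DEFAULT_BIN_WIDTHS = {
    "tmean": 1.0, "tmin": 1.0, "tmax": 1.0,   # degC
    "precip": 1.0,                            # mm/day, zero-inflated first bin
    "relhum": 5.0,                            # %
    "wind": 1.0,                              # m/s
}

#: How each metric is ranked: 'abs' = smaller magnitude better,
#: 'lower' = smaller better, 'higher' = larger better.
METRIC_ORIENTATION = {
    "bias": "abs",
    "pss": "higher",
    "mae_seasonal": "lower",
    "mae_percentile": "lower",
    "rmse": "lower",
    "spearman": "higher",
    "bss": "higher",
}


def _paired(model: pd.Series, obs: pd.Series, max_missing: float = 0.2):
    """Align two daily series on common dates and drop paired-missing days."""
    frame = pd.concat({"model": model, "obs": obs}, axis=1, join="inner")
    if frame.empty:
        raise ValueError("no overlapping period between model and observations")
    complete = frame.dropna()
    if complete.empty:
        raise ValueError("no paired non-missing days in the overlap")
    missing_frac = 1.0 - len(complete) / len(frame)
    if missing_frac > max_missing:
        raise ValueError(
            f"{missing_frac:.0%} of the overlap is missing "
            f"(limit {max_missing:.0%})"
        )
    return complete["model"], complete["obs"]


def mean_bias(model: pd.Series, obs: pd.Series, *, as_mm_per_year: bool = False) -> float:
    """mean(model) - mean(obs); optionally scaled to mm/year for precipitation."""
    m, o = _paired(model, obs)
    bias = float(m.mean() - o.mean())
    return bias * DAYS_PER_YEAR if as_mm_per_year else bias


def perkins_skill_score(
    model: pd.Series | np.ndarray,
    obs: pd.Series | np.ndarray,
    bin_width: float,
    *,
    zero_bin: float | None = None,
) -> float:
    """Overlap of two binned empirical distributions, in [0, 1].

    Shared bin edges span the pooled range; the score is the summed
    minimum of the two relative-frequency histograms and is symmetric
    in its arguments. ``zero_bin`` inserts a narrow first bin
    [0, zero_bin) to keep the dry-day spike of zero-inflated
    precipitation out of the first regular bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    m = np.asarray(model, dtype=float)
    o = np.asarray(obs, dtype=float)
    m, o = m[~np.isnan(m)], o[~np.isnan(o)]
    if m.size == 0 or o.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled_min = min(m.min(), o.min())
    pooled_max = max(m.max(), o.max())
    if zero_bin is not None:
        start = min(pooled_min, 0.0)
        edges = np.concatenate(
            [[start, zero_bin],
             np.arange(zero_bin + bin_width, pooled_max + bin_width, bin_width)]
        )
    else:
        start = np.floor(pooled_min / bin_width) * bin_width
        n_bins = max(1, int(np.ceil((pooled_max - start) / bin_width)) + 1)
        edges = start + bin_width * np.arange(n_bins + 1)
    fm = np.histogram(m, bins=edges)[0] / m.size
    fo = np.histogram(o, bins=edges)[0] / o.size
    return float(np.minimum(fm, fo).sum())


def seasonal_cycle(series: pd.Series) -> pd.Series:
    """Twelve monthly climatological means over the whole series."""
    clean = series.dropna()
    if clean.empty:
        raise ValueError("empty series")
    cycle = clean.groupby(clean.index.month).mean()
    if len(cycle) < 12:
        missing = sorted(set(range(1, 13)) - set(cycle.index))
        raise ValueError(f"no data for month(s) {missing}")
    return cycle.reindex(range(1, 13))


def seasonal_cycle_mae(model: pd.Series, obs: pd.Series) -> float:
    """Mean absolute difference of the two monthly seasonal cycles."""
    return float((seasonal_cycle(model) - seasonal_cycle(obs)).abs().mean())


def percentile_mae(
    model: pd.Series,
    obs: pd.Series,
    levels: tuple[float, ...] = (1, 10, 90, 99),
) -> float:
    """Mean absolute difference at the given daily-distribution percentiles.

    Percentiles use linear interpolation between order statistics.
    """
    m = np.asarray(model.dropna(), dtype=float)
    o = np.asarray(obs.dropna(), dtype=float)
    if m.size == 0 or o.size == 0:
        raise ValueError("both daily series must be non-empty")
    if min(m.size, o.size) < 100:
        warnings.warn(
            "fewer than 100 days available; tail percentiles are noisy",
            stacklevel=2,
        )
    qm = np.percentile(m, levels, method="linear")
    qo = np.percentile(o, levels, method="linear")
    return float(np.mean(np.abs(qm - qo)))


def rmse(model: pd.Series, obs: pd.Series) -> float:
    m, o = _paired(model, obs)
    return float(np.sqrt(np.mean((m.to_numpy() - o.to_numpy()) ** 2)))


def spearman_daily(model: pd.Series, obs: pd.Series) -> float:
    """Daily Spearman rank correlation (average ranks on ties)."""
    m, o = _paired(model, obs)
    if len(m) < 3:
        raise ValueError("need at least 3 paired values")
    if m.nunique() == 1 or o.nunique() == 1:
        raise ValueError("correlation undefined for a constant series")
    rho = stats.spearmanr(m, o).statistic
    return float(rho)


def _categorize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Category index (0..K-1) of each value given K-1 inner quantile edges."""
    return np.searchsorted(edges, values, side="right")


def brier_skill_score(model: pd.Series, obs: pd.Series, n_categories: int = 3) -> float:
    """Brier skill score of the model's categorical 'forecast' vs climatology.

    The observed days are split into ``n_categories`` equiprobable
    categories bounded by the observed climatological quantiles. The
    deterministic model assigns probability 1 to the category its own
    value falls in; the reference forecast assigns 1/K to every
    category. BSS = 1 - BS/BS_ref, with BS the Brier score averaged
    over days and categories. 1 means the model reproduces the observed
    categories exactly; 0 means no skill over climatology.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    m, o = _paired(model, obs)
    probs = np.arange(1, n_categories) / n_categories
    edges = np.quantile(o.to_numpy(), probs, method="linear")
    if np.unique(edges).size < edges.size:
        raise ValueError("degenerate climatological quantiles (near-constant obs)")
    obs_cat = _categorize(o.to_numpy(), edges)
    model_cat = _categorize(m.to_numpy(), edges)
    n, k = len(o), n_categories
    occurred = np.zeros((n, k))
    occurred[np.arange(n), obs_cat] = 1.0
    forecast = np.zeros((n, k))
    forecast[np.arange(n), model_cat] = 1.0
    bs = float(np.mean((forecast - occurred) ** 2))
    bs_ref = float(np.mean((1.0 / k - occurred) ** 2))
    return 1.0 - bs / bs_ref


_SEASON_MONTHS = {"annual": None, "DJF": (12, 1, 2), "JJA": (6, 7, 8)}


def _season_subset(frame: pd.DataFrame, season: str) -> pd.DataFrame:
    months = _SEASON_MONTHS[season]
    if months is None:
        return frame
    sub = frame[frame.index.month.isin(months)]
    if season == "DJF":
        # December belongs to the following winter; the final year's
        # December has no following Jan-Feb and is dropped.
        last_year = frame.index.year.max()
        sub = sub[~((sub.index.month == 12) & (sub.index.year == last_year))]
    if sub.empty:
        raise ValueError(f"season {season} subset is empty")
    return sub


def cross_correlation_table(
    model_daily: pd.DataFrame,
    obs_daily: pd.DataFrame,
    variables: tuple[str, ...] = ("tmean", "precip", "relhum", "wind"),
    seasons: tuple[str, ...] = ("annual", "DJF", "JJA"),
) -> pd.DataFrame:
    """Observed vs modelled Pearson correlations for all variable pairs.

    Returns a tidy frame (season, var1, var2, r_obs, r_model, abs_diff);
    the comparison value is |r_model - r_obs| per pair and season.
    """
    rows = []
    for season in seasons:
        msub = _season_subset(model_daily[list(variables)].dropna(), season)
        osub = _season_subset(obs_daily[list(variables)].dropna(), season)
        for v1, v2 in itertools.combinations(variables, 2):
            r_m = float(msub[v1].corr(msub[v2]))
            r_o = float(osub[v1].corr(osub[v2]))
            rows.append({
                "season": season, "var1": v1, "var2": v2,
                "r_obs": r_o, "r_model": r_m, "abs_diff": abs(r_m - r_o),
            })
    return pd.DataFrame(rows)


def skill_table(
    runs: dict[str, pd.DataFrame],
    obs: pd.DataFrame,
    *,
    daily_comparable: bool = True,
    bin_widths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Tidy skill table: one row per (run, variable, metric).

    ``daily_comparable=False`` suits GCM-driven runs, whose internal
    variability cannot be compared to observations day by day: RMSE,
    Spearman and BSS are then omitted, as is standard practice.
    Variables a run does not carry are skipped and simply absent from
    the table. Precipitation bias is additionally reported in mm/year.
    """
    widths = {**DEFAULT_BIN_WIDTHS, **(bin_widths or {})}
    rows = []
    for label, daily in runs.items():
        for var in obs.columns:
            if var not in daily.columns:
                continue
            m, o = daily[var], obs[var]
            zero_bin = 0.1 if var == "precip" else None
            entries = {
                "bias": mean_bias(m, o, as_mm_per_year=(var == "precip")),
                "pss": perkins_skill_score(m.dropna(), o.dropna(),
                                           widths[var], zero_bin=zero_bin),
                "mae_seasonal": seasonal_cycle_mae(m, o),
                "mae_percentile": percentile_mae(m, o),
            }
            if daily_comparable:
                entries["rmse"] = rmse(m, o)
                entries["spearman"] = spearman_daily(m, o)
                entries["bss"] = brier_skill_score(m, o)
            for metric, value in entries.items():
                rows.append({
                    "run": label, "variable": var, "metric": metric,
                    "value": value, "orientation": METRIC_ORIENTATION[metric],
                })
    return pd.DataFrame(rows)
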