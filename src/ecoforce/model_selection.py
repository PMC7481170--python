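"""Ranking, shortlisting and final selection of a representative model run.

The selection procedure is a reproducible version of the elimination
the method prescribes: per-metric 1-best..N-worst rankings, a composite
(weighted mean) rank per run, a shortlist of the best composites, a
representativeness screen that keeps candidates whose future anomalies
fall in a central band of the ensemble distribution, and a final choice
by minimum absolute precipitation bias — precipitation being the
decisive variable for ecosystem experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rank_column",
    "rank_skill_table",
    "diagnostic_differences",
    "aggregate_ranks",
    "shortlist",
    "anomaly_series",
    "ensemble_percentile_position",
    "select_final",
]


def rank_column(values: pd.Series, orientation: str) -> pd.Series:
    """1-best..N-worst integer ranks of per-run scores.

    ``orientation`` is ``'abs'`` (smaller magnitude is better, used for
    biases and diagnostic differences), ``'lower'`` (errors) or
    ``'higher'`` (skill scores). Ties take the smallest available rank
    in stable input order; runs with missing values are excluded and
    get a missing rank.
    """
    valid = values.dropna()
    if len(valid) < 2:
        raise ValueError("need at least 2 runs to rank")
    if orientation == "abs":
        key = valid.abs().to_numpy()
    elif orientation == "lower":
        key = valid.to_numpy(dtype=float)
    elif orientation == "higher":
        key = -valid.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    order = np.argsort(key, kind="stable")
    ranks = np.empty(len(valid), dtype=int)
    ranks[order] = np.arange(1, len(valid) + 1)
    out = pd.Series(ranks, index=valid.index, dtype=float)
    return out.reindex(values.index)


def rank_skill_table(skill: pd.DataFrame) -> pd.DataFrame:
    """Rank a tidy skill table within each (variable, metric) column.

    Input is the tidy frame from :func:`ecoforce.skill_metrics.skill_table`
    (run, variable, metric, value, orientation); output adds a ``rank``
    column.
    """
    out = skill.copy()
    out["rank"] = np.nan
    for (_, _), group in out.groupby(["variable", "metric"]):
        orientation = group["orientation"].iloc[0]
        col = pd.Series(group["value"].to_numpy(), index=group["run"].to_numpy())
        out.loc[group.index, "rank"] = rank_column(col, orientation).to_numpy()
    return out


def diagnostic_differences(
    run_diagnostics: dict[str, dict[str, float]],
    obs_diagnostics: dict[str, float],
) -> pd.DataFrame:
    """|model - observed| per (run, diagnostic); rank with orientation 'lower'."""
    rows = {}
    for label, diags in run_diagnostics.items():
        rows[label] = {
            name: abs(diags[name] - obs_value)
            for name, obs_value in obs_diagnostics.items()
            if name in diags
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_ranks(
    rank_table: pd.DataFrame,
    weights: dict[str, float] | None = None,
    subset: list[str] | None = None,
) -> pd.Series:
    """Weighted mean rank per run; lower is better.

    ``rank_table`` is wide (rows = runs, columns = rank columns). Runs
    missing some columns are averaged over their available columns with
    renormalised weights, so a run is never penalised for a variable it
    does not carry. Unit weights give the plain mean.
    """
    table = rank_table[subset] if subset is not None else rank_table
    w = pd.Series({c: (weights or {}).get(c, 1.0) for c in table.columns})
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    available = table.notna()
    weighted = (table * w).sum(axis=1, skipna=True)
    norm = (available * w).sum(axis=1)
    if (norm == 0).any():
        raise ValueError("some run has no rank in any selected column")
    return weighted / norm


def shortlist(
    scores: pd.Series, n: int, exclusions: list[str] | None = None
) -> list[str]:
    """The ``n`` runs with the best (lowest) composite scores, after exclusions."""
    if n <= 0:
        raise ValueError("n must be positive")
    kept = scores.drop(index=exclusions or [], errors="raise")
    if n > len(kept):
        raise ValueError(f"asked for {n} of {len(kept)} runs")
    return list(kept.sort_values(kind="stable").index[:n])


def anomaly_series(
    annual: pd.Series, reference: tuple[int, int] = (1977, 2006)
) -> pd.Series:
    """Annual anomalies of a run relative to its own reference-period mean."""
    ref = annual.loc[reference[0]:reference[1]]
    if ref.empty:
        raise ValueError(f"reference period {reference} outside series")
    return annual - ref.mean()


def ensemble_percentile_position(
    candidate: pd.Series,
    ensemble: dict[str, pd.Series],
    horizon: tuple[int, int],
) -> float:
    """Percentile of a candidate's horizon-mean anomaly within the ensemble.

    Each series is an anomaly series against the run's own reference
    period; the percentile interpolates linearly between the order
    statistics of the ensemble's horizon means (median of an odd
    ensemble maps to 50, a value below all members to 0).
    """
    if len(ensemble) < 3:
        raise ValueError("need an ensemble of at least 3 runs")
    means = np.sort([s.loc[horizon[0]:horizon[1]].mean() for s in ensemble.values()])
    value = candidate.loc[horizon[0]:horizon[1]].mean()
    positions = 100.0 * np.arange(len(means)) / (len(means) - 1)
    return float(np.interp(value, means, positions, left=0.0, right=100.0))


def select_final(
    candidates: list[str],
    precip_bias: pd.Series,
    percentile_positions: pd.DataFrame,
    band: tuple[float, float] = (25.0, 75.0),
    widen_step: float = 5.0,
) -> tuple[str, dict]:
    """Choose the forcing run: central-band screen, then minimum |P bias|.

    Candidates whose ensemble-percentile positions fall inside the
    central band for every anomaly variable are retained; among them
    the run with the smallest absolute precipitation bias (mm/yr) wins.
    An empty band is widened symmetrically until non-empty, and the
    widening is recorded in the returned report.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    lo, hi = band
    report: dict = {"band": band, "widened_to": None, "eliminated": []}
    while True:
        pos = percentile_positions.loc[candidates]
        in_band = ((pos >= lo) & (pos <= hi)).all(axis=1)
        retained = [c for c in candidates if in_band[c]]
        if retained:
            break
        lo, hi = max(lo - widen_step, 0.0), min(hi + widen_step, 100.0)
        report["widened_to"] = (lo, hi)
        if lo == 0.0 and hi == 100.0:
            retained = list(candidates)
            break
    report["eliminated"] = [c for c in candidates if c not in retained]
    chosen = precip_bias.loc[retained].abs().idxmin()
    report["retained"] = retained
    report["precip_bias_mm_yr"] = float(precip_bias.loc[chosen])
    return chosen, report
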