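"""Independent brute-force reference implementations used only by tests.

Every function here is written as a direct loop/enumeration transcription
of the definitions, deliberately avoiding the vectorised code paths of
the package so the two routes stay independent.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


# ---------------------------------------------------------------- skill

def bias_loop(model, obs) -> float:
    m, o = list(model), list(obs)
    return sum(m) / len(m) - sum(o) / len(o)


def pss_loop(model, obs, bin_width, zero_bin=None) -> float:
    m, o = list(model), list(obs)
    lo, hi = min(m + o), max(m + o)
    if zero_bin is not None:
        edges = [min(lo, 0.0), zero_bin]
        e = zero_bin + bin_width
        while e < hi + bin_width:
            edges.append(e)
            e += bin_width
    else:
        start = math.floor(lo / bin_width) * bin_width
        n = max(1, math.ceil((hi - start) / bin_width) + 1)
        edges = [start + bin_width * i for i in range(n + 1)]
    score = 0.0
    for left, right in zip(edges[:-1], edges[1:]):
        last = right == edges[-1]
        fm = sum(left <= v < right or (last and v == right) for v in m) / len(m)
        fo = sum(left <= v < right or (last and v == right) for v in o) / len(o)
        score += min(fm, fo)
    return score


def seasonal_cycle_loop(series: pd.Series) -> list[float]:
    out = []
    for month in range(1, 13):
        vals = [v for ts, v in series.items()
                if ts.month == month and not pd.isna(v)]
        out.append(sum(vals) / len(vals))
    return out


def percentile_loop(sample, level) -> float:
    """Linear interpolation between order statistics (type-7)."""
    s = sorted(sample)
    h = (len(s) - 1) * level / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def rmse_loop(model, obs) -> float:
    sq = [(m - o) ** 2 for m, o in zip(model, obs)]
    return math.sqrt(sum(sq) / len(sq))


def average_ranks(values) -> list[float]:
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def pearson_loop(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_loop(model, obs) -> float:
    return pearson_loop(average_ranks(list(model)), average_ranks(list(obs)))


def bss_loop(model, obs, k=3) -> float:
    o = list(obs)
    edges = [percentile_loop(o, 100.0 * j / k) for j in range(1, k)]

    def cat(v):
        # a value equal to an edge belongs to the upper category
        # (half-open bins [edge, next edge))
        c = 0
        for e in edges:
            if v >= e:
                c += 1
        return c

    bs = bs_ref = 0.0
    for mv, ov in zip(model, obs):
        oc, mc = cat(ov), cat(mv)
        for j in range(k):
            occurred = 1.0 if j == oc else 0.0
            forecast = 1.0 if j == mc else 0.0
            bs += (forecast - occurred) ** 2
            bs_ref += (1.0 / k - occurred) ** 2
    return 1.0 - bs / bs_ref


# --------------------------------------------------------------- indices

def count_loop(series, cmp, threshold) -> dict[int, float]:
    counts: dict[int, float] = {}
    for ts, v in series.items():
        hit = v > threshold if cmp == ">" else v < threshold
        counts[ts.year] = counts.get(ts.year, 0.0) + (1.0 if hit else 0.0)
    return counts


def rx1day_loop(precip: pd.Series) -> float:
    maxima: dict[tuple[int, int], float] = {}
    for ts, v in precip.items():
        key = (ts.year, ts.month)
        maxima[key] = max(maxima.get(key, -math.inf), v)
    vals = list(maxima.values())
    return sum(vals) / len(vals)


def spell_loop(precip: pd.Series, kind: str) -> dict[int, float]:
    best: dict[int, float] = {}
    run = 0
    prev_year = None
    for ts, v in precip.items():
        if ts.year != prev_year:
            run = 0
            prev_year = ts.year
            best.setdefault(ts.year, 0.0)
        flag = v < 1.0 if kind == "dry" else v >= 1.0
        run = run + 1 if flag else 0
        best[ts.year] = max(best[ts.year], run)
    return best


def gsl_loop(tmean_year: pd.Series, span=6) -> float:
    t = list(tmean_year)
    months = [ts.month for ts in tmean_year.index]
    warm_start = None
    run = 0
    for i, v in enumerate(t):
        run = run + 1 if v > 5.0 else 0
        if run == span:
            warm_start = i - span + 1
            break
    if warm_start is None:
        return 0.0
    july1 = months.index(7)
    cold_start = None
    run = 0
    for i in range(max(july1, warm_start), len(t)):
        run = run + 1 if t[i] < 5.0 else 0
        if run == span:
            cold_start = i - span + 1
            break
    end = len(t) if cold_start is None else cold_start
    return float(max(end - warm_start, 0))


def prcptot_loop(precip: pd.Series) -> dict[int, float]:
    out: dict[int, float] = {}
    for ts, v in precip.items():
        out[ts.year] = out.get(ts.year, 0.0) + v
    return out


def extremes_loop(tmax: pd.Series, tmin: pd.Series):
    txx: dict[int, float] = {}
    tnn: dict[int, float] = {}
    for ts, v in tmax.items():
        txx[ts.year] = max(txx.get(ts.year, -math.inf), v)
    for ts, v in tmin.items():
        tnn[ts.year] = min(tnn.get(ts.year, math.inf), v)
    return txx, tnn


def dtr_loop(tmax, tmin, months=None) -> float:
    diffs = [a - b for (ts, a), b in zip(tmax.items(), tmin)
             if months is None or ts.month in months]
    return sum(diffs) / len(diffs)


# --------------------------------------------------------------- forcing

def two_point_line(t0, v0, t1, v1, t):
    return v0 + (v1 - v0) * (t - t0) / (t1 - t0)


def drizzle_trace(amounts, threshold=1.0):
    out, buffer = [], 0.0
    for a in amounts:
        if buffer + a < threshold:
            buffer += a
            out.append(0.0)
        else:
            out.append(buffer + a)
            buffer = 0.0
    return out, buffer


# ------------------------------------------------------------------ misc

def running_mean_loop(values, window, past, future):
    """Centred running mean by explicit slicing; returns (positions, means)."""
    out = []
    for i in range(past, len(values) - future):
        chunk = values[i - past:i + future + 1]
        out.append(sum(chunk) / window)
    return out


def percentile_position_loop(value, sample) -> float:
    s = sorted(sample)
    if value <= s[0]:
        return 0.0
    if value >= s[-1]:
        return 100.0
    for i in range(len(s) - 1):
        if s[i] <= value <= s[i + 1]:
            frac = 0.0 if s[i + 1] == s[i] else (value - s[i]) / (s[i + 1] - s[i])
            return 100.0 * (i + frac) / (len(s) - 1)
    raise AssertionError


def weighted_mean_loop(values, weights):
    num = sum(v * w for v, w in zip(values, weights) if not np.isnan(v))
    den = sum(w for v, w in zip(values, weights) if not np.isnan(v))
    return num / den
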