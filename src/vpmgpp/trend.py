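"""Seasonal Mann-Kendall test and seasonal Theil-Sen slope.

Trends in the 8-day (or monthly) GPP product are assessed
nonparametrically within each season — here a "season" is one of the
46 composite indices (or 12 months) — so the strong seasonal cycle
never masquerades as a trend.  The Mann-Kendall S statistic and its
tie-corrected variance are computed per season and summed; the p-value
uses the normal approximation with continuity correction.  The slope
is the median of all within-season pairwise slopes pooled across
seasons, in units of the input per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

DEFAULT_ALPHA = 0.05


@dataclass
class TrendResult:
    slope: float  # input units per year
    s_statistic: int
    p_value: float
    significant: bool


def _check_series(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, float)
    if series.ndim != 2:
        raise ValueError("series must be (n_years, n_seasons)")
    return series


def seasonal_theil_sen(series: np.ndarray) -> float:
    """Median of pooled within-season pairwise slopes.

    ``series`` is (n_years, n_seasons); years are assumed consecutive
    (unit spacing).  NaNs drop out pairwise.  Needs at least one
    season with two finite years.
    """
    series = _check_series(series)
    n_years = series.shape[0]
    if n_years < 2:
        raise ValueError("need at least 2 years")
    years = np.arange(n_years, dtype=float)
    i, j = np.triu_indices(n_years, k=1)
    slopes = (series[j, :] - series[i, :]) / (years[j] - years[i])[:, None]
    slopes = slopes[np.isfinite(slopes)]
    if slopes.size == 0:
        raise ValueError("no finite within-season pairs")
    return float(np.median(slopes))


def _mk_season(values: np.ndarray) -> tuple[int, float]:
    """(S, var(S)) for one season's annual values (NaNs dropped)."""
    v = values[np.isfinite(values)]
    n = v.size
    if n < 2:
        return 0, 0.0
    diff = np.sign(v[None, :] - v[:, None])
    s = int(np.triu(diff, k=1).sum())
    var = n * (n - 1) * (2 * n + 5) / 18.0
    _, counts = np.unique(v, return_counts=True)
    ties = counts[counts > 1]
    var -= (ties * (ties - 1) * (2 * ties + 5)).sum() / 18.0
    return s, var


def seasonal_mann_kendall(series: np.ndarray, alpha: float = DEFAULT_ALPHA) -> TrendResult:
    """Seasonal Mann-Kendall trend test with Theil-Sen slope.

    S and its tie-corrected variance are summed over seasons
    (independence across seasons assumed); the two-sided p-value uses
    Z = (S -/+ 1)/sqrt(Var) with continuity correction.  An all-tied
    series returns S=0, slope 0, p=1.
    """
    series = _check_series(series)
    if np.isfinite(series).sum(axis=0).max(initial=0) < 3:
        raise ValueError("need at least 3 years in some season")
    s_total, var_total = 0, 0.0
    for season in range(series.shape[1]):
        s, var = _mk_season(series[:, season])
        s_total += s
        var_total += var
    if var_total == 0:
        return TrendResult(slope=0.0, s_statistic=0, p_value=1.0, significant=False)
    if s_total > 0:
        z = (s_total - 1) / np.sqrt(var_total)
    elif s_total < 0:
        z = (s_total + 1) / np.sqrt(var_total)
    else:
        z = 0.0
    p = float(2.0 * norm.sf(abs(z)))
    try:
        slope = seasonal_theil_sen(series)
    except ValueError:
        slope = 0.0
    return TrendResult(
        slope=slope, s_statistic=s_total, p_value=p, significant=p < alpha
    )


def trend_raster(cube: np.ndarray, alpha: float = DEFAULT_ALPHA):
    """Per-pixel seasonal trend over a (n_years, n_seasons, rows, cols)
    stack; returns (slope, p_value, significant) rasters."""
    cube = np.asarray(cube, float)
    if cube.ndim != 4:
        raise ValueError("cube must be (years, seasons, rows, cols)")
    ny, ns, rows, cols = cube.shape
    slope = np.full((rows, cols), np.nan)
    pval = np.full((rows, cols), np.nan)
    sig = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            series = cube[:, :, r, c]
            if np.isfinite(series).sum(axis=0).max(initial=0) < 3:
                continue
            res = seasonal_mann_kendall(series, alpha)
            slope[r, c] = res.slope
            pval[r, c] = res.p_value
            sig[r, c] = res.significant
    return slope, pval, sig
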