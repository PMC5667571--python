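"""MODIS 8-day composite calendar arithmetic.

The year is partitioned into 46 compositing windows starting at DOY
1, 9, ..., 361.  Windows 1-45 span 8 days; window 46 spans the 5 (6 in
leap years) days left at the end of the year.  These helpers are shared
by the climate aggregation and by the monthly/annual product builders so
the day-weighted partition identity (sum of monthly totals == annual
total) holds exactly.
"""

from __future__ import annotations

import calendar as _cal

import numpy as np

N_COMPOSITES = 46


def is_leap(year: int) -> bool:
    return _cal.isleap(year)


def year_length(year: int) -> int:
    return 366 if is_leap(year) else 365


def composite_start_doy(index: int) -> int:
    """First DOY of composite ``index`` (1-based, 1..46)."""
    if not 1 <= index <= N_COMPOSITES:
        raise ValueError(f"composite index must be in 1..46, got {index}")
    return 8 * (index - 1) + 1


def composite_days(index: int, year: int) -> int:
    """Number of days covered by composite ``index`` in ``year``."""
    start = composite_start_doy(index)
    end = min(8 * index, year_length(year))
    return end - start + 1


def composite_doy_range(index: int, year: int) -> tuple[int, int]:
    """Inclusive (first, last) DOY covered by a composite."""
    start = composite_start_doy(index)
    return start, start + composite_days(index, year) - 1


def composite_of_doy(doy: int, year: int) -> int:
    """Composite index (1..46) containing a day of year."""
    if not 1 <= doy <= year_length(year):
        raise ValueError(f"DOY {doy} out of range for year {year}")
    return min((doy - 1) // 8 + 1, N_COMPOSITES)


def all_composite_days(year: int) -> np.ndarray:
    """Length-46 array of day counts; sums to the year length."""
    return np.array([composite_days(k, year) for k in range(1, N_COMPOSITES + 1)])


def month_of_doy(doy: int, year: int) -> int:
    month_ends = np.cumsum([_cal.monthrange(year, m)[1] for m in range(1, 13)])
    return int(np.searchsorted(month_ends, doy) + 1)


def days_in_month(month: int, year: int) -> int:
    return _cal.monthrange(year, month)[1]


def composite_month_weights(year: int) -> np.ndarray:
    """(46, 12) matrix: number of days composite k contributes to month m.

    Composites straddling a month boundary are split day-by-day, so each
    row sums to the composite length and each column to the month length.
    """
    weights = np.zeros((N_COMPOSITES, 12), dtype=int)
    for k in range(1, N_COMPOSITES + 1):
        first, last = composite_doy_range(k, year)
        for doy in range(first, last + 1):
            weights[k - 1, month_of_doy(doy, year) - 1] += 1
    return weights
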