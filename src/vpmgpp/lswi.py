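"""LSWI series preparation and the smoothed annual LSWI_max.

LSWI is deliberately not pushed through the EVI anomaly gap-filler:
surface water, snow and residual cloud raise LSWI rather than lowering
it, the index's year-to-year variance is the water-stress signal
itself, and atmospheric contamination affects it less than EVI.  Years
with systematically missing acquisitions are instead patched by copying
the same composite index from a designated donor year.

The water scalar needs a per-pixel LSWI_max: the maximum LSWI over the
snow-free part of each year, then smoothed over a centered five-year
window by taking the *second largest* of the annual maxima, which
strips single-year upward artifacts without dragging the ceiling down.
"""

from __future__ import annotations

import numpy as np

from .compositing import N_COMPOSITES
from .indices import VISeries

# Donor years for target years with missing acquisitions in the MODIS
# Terra record: 2000 and 2001 are patched forward, 2016 backward.
DEFAULT_YEAR_SUBSTITUTION = {2000: 2001, 2001: 2002, 2016: 2015}


def substitute_missing_years(
    vi: VISeries, substitution_map: dict[int, int] | None = None
) -> VISeries:
    """Replace missing LSWI composites from donor years.

    Each invalid composite of a target year takes the value of the same
    composite index in its mapped donor year.  Donor composites must be
    valid where used; targets absent from the map are left alone.
    """
    if substitution_map is None:
        substitution_map = DEFAULT_YEAR_SUBSTITUTION
    out = vi.copy()
    index = {yc: i for i, yc in enumerate(vi.calendar)}
    years = set(vi.years)
    for target, source in substitution_map.items():
        if target not in years:
            continue
        if source not in years:
            raise ValueError(f"substitution source year {source} not in series")
        for k in range(1, N_COMPOSITES + 1):
            ti = index.get((target, k))
            si = index.get((source, k))
            if ti is None:
                continue
            if si is None:
                raise ValueError(f"source year {source} missing composite {k}")
            need = ~out.lswi_valid[ti]
            if need.any():
                if not vi.lswi_valid[si][need].all():
                    raise ValueError(
                        f"source year {source} composite {k} invalid where needed"
                    )
                out.lswi[ti] = np.where(need, vi.lswi[si], out.lswi[ti])
                out.lswi_valid[ti] |= need
    return out


def snowfree_mask(qa_flags, night_lst: np.ndarray | None = None) -> np.ndarray:
    """Snow-free observation mask for the LSWI_max search.

    A composite is snow-free when the QA snow/ice flag is unset and,
    when a nighttime LST composite is supplied, the surface stayed
    above freezing (LST > 0 degC).  The LST criterion guards against
    snow the QA screen missed and is optional.
    """
    mask = ~qa_flags.snow_ice
    if night_lst is not None:
        mask = mask & (np.asarray(night_lst, float) > 0.0)
    return mask


def annual_lswi_max(lswi: np.ndarray, valid: np.ndarray, snowfree: np.ndarray) -> np.ndarray:
    """Raw annual maximum LSWI over snow-free valid composites.

    Input arrays are (46, ...); pixels with no snow-free valid
    composite get NaN and drop out of the smoothing window.
    """
    usable = np.asarray(valid, bool) & np.asarray(snowfree, bool)
    masked = np.where(usable, np.asarray(lswi, float), -np.inf)
    top = masked.max(axis=0)
    return np.where(np.isfinite(top), top, np.nan)


def second_largest(values: np.ndarray) -> float:
    """Second largest of a 1-D multiset (duplicates count separately);
    the single value itself if only one is present."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.nan
    if values.size == 1:
        return float(values[0])
    return float(np.sort(values)[-2])


def smooth_lswi_max(raw_maxima: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Five-year second-largest smoothing of annual LSWI maxima.

    ``raw_maxima`` is (n_years, ...) with NaN for excluded pixel-years.
    For each year the window [y-2, y+2] is truncated at the ends of the
    record; the smoothed value is the second largest valid maximum in
    the window (the largest is treated as a potential artifact), or the
    lone value when only one is available.
    """
    raw = np.asarray(raw_maxima, float)
    n_years = raw.shape[0]
    out = np.full_like(raw, np.nan)
    flat = raw.reshape(n_years, -1)
    out_flat = out.reshape(n_years, -1)
    for y in range(n_years):
        lo, hi = max(0, y - half_window), min(n_years, y + half_window + 1)
        win = flat[lo:hi]
        finite = np.isfinite(win)
        n_valid = finite.sum(axis=0)
        neg = np.where(finite, win, -np.inf)
        top = neg.max(axis=0)
        # second largest = max after removing one copy of the max
        first_max = neg.argmax(axis=0)
        trimmed = neg.copy()
        trimmed[first_max, np.arange(win.shape[1])] = -np.inf
        second = np.where(n_valid >= 2, trimmed.max(axis=0), top)
        out_flat[y] = np.where(n_valid >= 1, second, np.nan)
    return out
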