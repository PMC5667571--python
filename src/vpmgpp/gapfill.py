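"""Reference-curve / seasonal-anomaly EVI gap-filling.

Cloud- and aerosol-masked EVI series are reconstructed per pixel in
four steps:

1. Within each pixel-year, implausible downward spikes that the QA
   screen missed are rejected with a Best Index Slope Extraction (BISE)
   rule: a drop that "recovers" within a short sliding window is
   contamination, a persistent decline is real senescence.
2. A per-pixel reference seasonal curve is built as the median of all
   surviving observations for each of the 46 composite indices across
   years; composite indices with no observation at all are filled by
   linear interpolation on the circular seasonal axis and the curve is
   smoothed with a Savitzky-Golay filter.
3. Each year's deviation from the reference (the seasonal anomaly) is
   linearly interpolated across its gaps and Savitzky-Golay smoothed.
4. The filled anomaly is added back to the reference.

Interpolating anomalies rather than raw EVI lets long gaps follow the
climatological seasonal shape instead of a straight line, which matters
when green-up or senescence happens inside the gap (e.g. the missing
start of the Terra record in early 2000).  A pixel with valid
observations for fewer than half of the 46 composite indices is
declared unfillable and propagates nodata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .compositing import N_COMPOSITES
from .indices import VISeries

# Defaults; the source filter/algorithm parameters are not standardized,
# so all are exposed.
SG_WINDOW = 7
SG_ORDER = 2
BISE_WINDOW = 5  # composites (~40 days)
BISE_RECOVERY_FRACTION = 0.2
BISE_MIN_DROP_FRACTION = 0.2  # only drops > 20% of the baseline are spike candidates
MIN_VALID_COMPOSITE_FRACTION = 0.5


@dataclass
class ReferenceCurve:
    """Median seasonal EVI curve per pixel.

    ``median`` holds the raw per-composite medians (NaN where no year
    had a valid observation); ``values`` is the completed curve after
    circular interpolation and smoothing; ``count`` the number of valid
    observations behind each median; ``fillable`` marks pixels with
    enough seasonal coverage to reconstruct.
    """

    values: np.ndarray  # (46, ...) complete
    median: np.ndarray  # (46, ...) raw medians with NaN
    count: np.ndarray  # (46, ...) int
    fillable: np.ndarray  # (...,) bool


def bise_filter(
    values: np.ndarray,
    valid: np.ndarray,
    window: int = BISE_WINDOW,
    recovery_fraction: float = BISE_RECOVERY_FRACTION,
    min_drop_fraction: float = BISE_MIN_DROP_FRACTION,
) -> np.ndarray:
    """Spike mask for one pixel-year EVI series (True = keep).

    A valid point that drops by more than ``min_drop_fraction`` of the
    last accepted value is rejected when any later valid point within
    ``window`` composites exceeds the low value plus
    ``recovery_fraction`` of the drop — a sudden dip followed by a
    quick rebound marks residual cloud/aerosol contamination.  The
    minimum-drop criterion keeps the gentle decline into (and out of)
    the seasonal trough, where tiny steps always "recover", from being
    misread as spikes.  Rejections cascade: the comparison baseline is
    the last *accepted* point, so a run of contaminated composites is
    removed as a whole.
    """
    values = np.asarray(values, float)
    keep = np.asarray(valid, bool).copy()
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        return keep
    last_accepted = idx[0]
    for j in range(1, idx.size):
        i = idx[j]
        drop = values[last_accepted] - values[i]
        if drop > min_drop_fraction * abs(values[last_accepted]):
            threshold = values[i] + recovery_fraction * drop
            recovered = False
            for k in idx[j + 1 :]:
                if k - i > window:
                    break
                if values[k] > threshold:
                    recovered = True
                    break
            if recovered:
                keep[i] = False
                continue
        last_accepted = i
    return keep


def interpolate_gaps(values: np.ndarray, valid: np.ndarray, circular: bool = False) -> np.ndarray:
    """Linear interpolation across invalid entries of a 1-D series.

    Ends are extended with the nearest valid value; with
    ``circular=True`` the axis wraps (composite 46 adjacent to 1).
    """
    values = np.asarray(values, float)
    valid = np.asarray(valid, bool)
    n = values.size
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise ValueError("cannot interpolate a series with no valid points")
    if idx.size == n:
        return values.copy()
    x = np.arange(n, dtype=float)
    if circular:
        return np.interp(x, idx.astype(float), values[idx], period=float(n))
    return np.interp(x, idx.astype(float), values[idx])


def sg_smooth(values: np.ndarray, window: int = SG_WINDOW, order: int = SG_ORDER,
              axis: int = -1, wrap: bool = False) -> np.ndarray:
    """Savitzky-Golay filter; ``wrap`` treats the axis as circular."""
    return savgol_filter(values, window, order, axis=axis,
                         mode="wrap" if wrap else "interp")


def interpolate_and_smooth(
    values: np.ndarray,
    valid: np.ndarray,
    window: int = SG_WINDOW,
    order: int = SG_ORDER,
) -> np.ndarray:
    """Gap-fill one series by linear interpolation, then SG smoothing.

    Requires at least two valid points; fewer makes the series
    unfillable at this level (callers decide the fallback).
    """
    if np.count_nonzero(valid) < 2:
        raise ValueError("need >=2 valid points to interpolate and smooth")
    return sg_smooth(interpolate_gaps(values, valid), window, order)


def build_reference(
    evi: np.ndarray,
    valid: np.ndarray,
    window: int = SG_WINDOW,
    order: int = SG_ORDER,
    min_fraction: float = MIN_VALID_COMPOSITE_FRACTION,
) -> ReferenceCurve:
    """Median seasonal curve from a (years, 46, ...) EVI stack.

    The median over years is taken composite-by-composite (median of an
    even count = mean of the two central values, numpy convention);
    seasonally empty composites are filled by circular linear
    interpolation and the completed curve is SG-smoothed on the
    circular axis.  Pixels with valid data for less than
    ``min_fraction`` of composite indices are marked unfillable.
    """
    evi = np.asarray(evi, float)
    valid = np.asarray(valid, bool)
    if evi.shape[1] != N_COMPOSITES:
        raise ValueError(f"expected axis 1 of length {N_COMPOSITES}, got {evi.shape}")
    masked = np.where(valid, evi, np.nan)
    with warnings.catch_warnings():
        # composites with no valid year legitimately yield NaN medians
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(masked, axis=0)
    count = valid.sum(axis=0)
    covered = count > 0
    fillable = covered.mean(axis=0) >= min_fraction

    flat_median = median.reshape(N_COMPOSITES, -1)
    flat_covered = covered.reshape(N_COMPOSITES, -1)
    flat_fillable = fillable.reshape(-1)
    values = flat_median.copy()
    for p in np.flatnonzero(flat_fillable):
        col_cov = flat_covered[:, p]
        if not col_cov.all():
            values[:, p] = interpolate_gaps(flat_median[:, p], col_cov, circular=True)
    values[:, ~flat_fillable] = np.nan
    if flat_fillable.any():
        values[:, flat_fillable] = sg_smooth(
            values[:, flat_fillable], window, order, axis=0, wrap=True
        )
    return ReferenceCurve(
        values=values.reshape(median.shape),
        median=median,
        count=count,
        fillable=fillable,
    )


def fill_anomalies(
    year_evi: np.ndarray,
    valid: np.ndarray,
    reference: np.ndarray,
    window: int = SG_WINDOW,
    order: int = SG_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct one pixel-year from its seasonal anomalies.

    Returns (filled series, gap-fill flags).  Flags are True wherever
    the observation was not a valid raw value.  With no valid points
    the output is the reference itself; with one, the single anomaly is
    carried as a constant offset.
    """
    year_evi = np.asarray(year_evi, float)
    valid = np.asarray(valid, bool)
    reference = np.asarray(reference, float)
    flags = ~valid
    n_valid = np.count_nonzero(valid)
    if n_valid == 0:
        return reference.copy(), flags
    anomaly = year_evi - reference
    if n_valid == 1:
        filled = np.full_like(reference, anomaly[valid][0])
    else:
        filled = interpolate_and_smooth(anomaly, valid, window, order)
    return reference + filled, flags


def reconstruct_evi(
    vi: VISeries,
    window: int = SG_WINDOW,
    order: int = SG_ORDER,
    bise_window: int = BISE_WINDOW,
    bise_recovery_fraction: float = BISE_RECOVERY_FRACTION,
    bise_min_drop_fraction: float = BISE_MIN_DROP_FRACTION,
    min_fraction: float = MIN_VALID_COMPOSITE_FRACTION,
) -> tuple[VISeries, np.ndarray, ReferenceCurve]:
    """Full gap-fill of a masked multi-year EVI cube.

    Orchestrates BISE -> reference -> per-year anomaly filling for every
    pixel and returns (filled series, gap-fill flag cube, reference).
    The filled series has no missing values on fillable pixels;
    unfillable pixels stay NaN with flags set.  The flag cube is True
    exactly where the output did not come from a surviving raw
    observation, matching the product's Boolean QA layer.
    """
    years = vi.years
    n_years = len(years)
    expected = [(y, k) for y in years for k in range(1, N_COMPOSITES + 1)]
    if vi.calendar != expected:
        raise ValueError("VISeries calendar must be complete years in order")
    spatial = vi.evi.shape[1:]
    n_pix = int(np.prod(spatial))
    evi = vi.evi.reshape(n_years, N_COMPOSITES, n_pix)
    valid = vi.evi_valid.reshape(n_years, N_COMPOSITES, n_pix).copy()

    for y in range(n_years):
        for p in range(n_pix):
            v = valid[y, :, p]
            if v.any():
                valid[y, :, p] = bise_filter(
                    evi[y, :, p], v, bise_window, bise_recovery_fraction,
                    bise_min_drop_fraction,
                )

    ref = build_reference(evi, valid, window, order, min_fraction)
    ref_flat = ref.values.reshape(N_COMPOSITES, n_pix)
    fillable = ref.fillable.reshape(n_pix)

    filled = np.full((n_years, N_COMPOSITES, n_pix), np.nan)
    flags = np.ones((n_years, N_COMPOSITES, n_pix), dtype=bool)
    # Fill anomalies with linear interpolation per series, then smooth
    # all series in one vectorized SG pass.
    anomalies = np.zeros((n_years, N_COMPOSITES, n_pix))
    for p in np.flatnonzero(fillable):
        for y in range(n_years):
            v = valid[y, :, p]
            flags[y, :, p] = ~v
            n_valid = int(v.sum())
            if n_valid == 0:
                anomalies[y, :, p] = 0.0
            elif n_valid == 1:
                anomalies[y, :, p] = (evi[y, :, p] - ref_flat[:, p])[v][0]
            else:
                anomalies[y, :, p] = interpolate_gaps(
                    evi[y, :, p] - ref_flat[:, p], v
                )
    if fillable.any():
        cols = np.flatnonzero(fillable)
        smoothed = sg_smooth(anomalies[:, :, cols], window, order, axis=1)
        filled[:, :, cols] = ref_flat[None, :, cols] + smoothed

    out = vi.copy()
    out.evi = filled.reshape(vi.evi.shape)
    out.evi_valid = np.isfinite(out.evi)
    flag_cube = flags.reshape(vi.evi.shape)
    ref = ReferenceCurve(
        values=ref.values.reshape((N_COMPOSITES,) + spatial),
        median=ref.median.reshape((N_COMPOSITES,) + spatial),
        count=ref.count.reshape((N_COMPOSITES,) + spatial),
        fillable=ref.fillable.reshape(spatial),
    )
    return out, flag_cube, ref
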