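"""Coarse-grid daily climate to tile-resolution 8-day forcing.

Daily reanalysis fields (downward shortwave radiation, daily maximum
and mean 2-m air temperature) are reduced to the model's drivers in
three steps: a daytime-temperature proxy per day, temporal averaging
onto the 46-composite calendar, and bilinear spatial downscaling from
the coarse cell centers to the tile pixel centers.  Aggregation runs
before interpolation; both operations are linear so the order does not
change the result, and the coarse-grid average is far cheaper.

PAR is derived from shortwave flux as

    PAR [mol m-2 day-1] = dswrf [W m-2] * f_par * q * 86400 * 1e-6

with f_par the PAR fraction of shortwave energy (default 0.45) and q
the quantum content of PAR (default 4.57 umol/J).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .compositing import N_COMPOSITES, all_composite_days, year_length
from .grids import GridGeometry

PAR_FRACTION_OF_SHORTWAVE = 0.45
PAR_QUANTA_PER_JOULE = 4.57  # umol photons per joule of PAR
SECONDS_PER_DAY = 86400.0


@dataclass
class ClimateForcing:
    """8-day PAR and daytime temperature on the tile grid.

    ``par``: mol photons m-2 day-1, ``t_day``: degC; both shaped
    (n_years * 46, rows, cols) on the same calendar as the VI series.
    """

    par: np.ndarray
    t_day: np.ndarray
    calendar: list[tuple[int, int]]


def daytime_temperature(tmax_daily: np.ndarray, tmean_daily: np.ndarray) -> np.ndarray:
    """Daytime temperature proxy: mean of daily maximum and daily mean."""
    tmax = np.asarray(tmax_daily, float)
    tmean = np.asarray(tmean_daily, float)
    return (tmax + tmean) / 2.0


def aggregate_8day(daily_field: np.ndarray, year: int) -> np.ndarray:
    """Average a complete daily series onto the 46-composite calendar.

    ``daily_field`` has the day axis first (length 365/366).  Composite
    k averages DOY 8(k-1)+1 .. min(8k, year end); the last window is 5
    days (6 in leap years).  Day-weighting the 46 means recovers the
    annual daily mean exactly.
    """
    daily = np.asarray(daily_field, float)
    n_days = year_length(year)
    if daily.shape[0] != n_days:
        raise ValueError(
            f"year {year} needs {n_days} days, got {daily.shape[0]}"
        )
    if not np.isfinite(daily).all():
        missing = np.unique(np.nonzero(~np.isfinite(daily))[0]) + 1
        raise ValueError(f"missing daily values at DOY {missing.tolist()}")
    days = all_composite_days(year)
    edges = np.concatenate([[0], np.cumsum(days)])
    out = np.empty((N_COMPOSITES,) + daily.shape[1:])
    for k in range(N_COMPOSITES):
        out[k] = daily[edges[k] : edges[k + 1]].mean(axis=0)
    return out


def shortwave_to_par(
    dswrf: np.ndarray,
    par_fraction: float = PAR_FRACTION_OF_SHORTWAVE,
    quanta_per_joule: float = PAR_QUANTA_PER_JOULE,
) -> np.ndarray:
    """Convert downward shortwave flux (W m-2) to PAR (mol m-2 day-1)."""
    dswrf = np.asarray(dswrf, float)
    if (dswrf < 0).any():
        raise ValueError("negative shortwave flux")
    return dswrf * par_fraction * quanta_per_joule * SECONDS_PER_DAY * 1e-6


def downscale_to_grid(
    coarse_field: np.ndarray,
    coarse_lon: np.ndarray,
    coarse_lat: np.ndarray,
    target: GridGeometry,
) -> np.ndarray:
    """Bilinear interpolation of coarse cell-center values to tile pixels.

    ``coarse_field`` may carry leading axes (time, ...); the last two
    are (lat, lon).  Pixels outside the coarse cell-center hull take
    the nearest-edge value (coordinates are clamped to the hull), so a
    grid covering the tile bounding box with a one-cell margin is
    enough.
    """
    coarse_lon = np.asarray(coarse_lon, float)
    coarse_lat = np.asarray(coarse_lat, float)
    lon_t = target.lon_centers()
    lat_t = target.lat_centers()
    lon_min, lat_min, lon_max, lat_max = target.bounds()
    if coarse_lon.min() > lon_min or coarse_lon.max() < lon_max or \
       coarse_lat.min() > lat_min or coarse_lat.max() < lat_max:
        # tolerate up to one coarse cell of clamping at the edges
        dlon = np.diff(np.sort(coarse_lon)).max()
        dlat = np.diff(np.sort(coarse_lat)).max()
        if (coarse_lon.min() - dlon > lon_min or coarse_lon.max() + dlon < lon_max
                or coarse_lat.min() - dlat > lat_min or coarse_lat.max() + dlat < lat_max):
            raise ValueError("coarse grid does not cover the target tile")
    field = np.asarray(coarse_field, float)
    lead = field.shape[:-2]
    flat = field.reshape((-1,) + field.shape[-2:])

    lat_order = np.argsort(coarse_lat)
    lon_order = np.argsort(coarse_lon)
    lat_sorted = coarse_lat[lat_order]
    lon_sorted = coarse_lon[lon_order]
    lat_q = np.clip(lat_t, lat_sorted[0], lat_sorted[-1])
    lon_q = np.clip(lon_t, lon_sorted[0], lon_sorted[-1])
    pts_lat, pts_lon = np.meshgrid(lat_q, lon_q, indexing="ij")
    query = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])

    out = np.empty(lead + target.shape) if lead else np.empty(target.shape)
    out_flat = out.reshape((-1,) + target.shape)
    for i in range(flat.shape[0]):
        interp = RegularGridInterpolator(
            (lat_sorted, lon_sorted),
            flat[i][np.ix_(lat_order, lon_order)],
            method="linear",
        )
        out_flat[i] = interp(query).reshape(target.shape)
    return out


def prepare_forcing(
    dswrf_daily: dict[int, np.ndarray],
    tmax_daily: dict[int, np.ndarray],
    tmean_daily: dict[int, np.ndarray],
    coarse_lon: np.ndarray,
    coarse_lat: np.ndarray,
    target: GridGeometry,
    par_fraction: float = PAR_FRACTION_OF_SHORTWAVE,
    quanta_per_joule: float = PAR_QUANTA_PER_JOULE,
) -> ClimateForcing:
    """Full forcing preparation for a set of years.

    Inputs are per-year dicts of daily coarse-grid fields shaped
    (n_days, n_lat, n_lon).  Output stacks 46 composites per year in
    calendar order on the tile grid.
    """
    years = sorted(dswrf_daily)
    par_layers, t_layers, calendar = [], [], []
    for year in years:
        par_8d = aggregate_8day(
            shortwave_to_par(dswrf_daily[year], par_fraction, quanta_per_joule), year
        )
        t_8d = aggregate_8day(
            daytime_temperature(tmax_daily[year], tmean_daily[year]), year
        )
        par_layers.append(downscale_to_grid(par_8d, coarse_lon, coarse_lat, target))
        t_layers.append(downscale_to_grid(t_8d, coarse_lon, coarse_lat, target))
        calendar.extend((year, k) for k in range(1, N_COMPOSITES + 1))
    return ClimateForcing(
        par=np.concatenate(par_layers, axis=0),
        t_day=np.concatenate(t_layers, axis=0),
        calendar=calendar,
    )
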