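"""Self-contained synthetic inputs with retained ground truth.

Every pipeline stage can be exercised without downloading satellite or
reanalysis data: this module fabricates a small tile (default 50 x 50
pixels, 3 years) of MOD09A1-like reflectance composites whose bands are
*inverted* from a known truth EVI/LSWI phenology, a matching QA bit
field with spatially/temporally clustered cloud gaps, coarse-grid daily
climate with realistic mid-latitude ranges, a patchy IGBP land-cover
raster, and C4 fraction maps at their native 0.083- and 1-degree
resolutions.  The noise-free truth fields are kept alongside so
recovery tests can measure reconstruction error; pipeline stages never
see them.

All generators are pure functions of (spec, seed): the same spec gives
bit-identical fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .compositing import N_COMPOSITES, composite_start_doy, year_length
from .grids import GridGeometry
from .indices import QA_DIALECTS, ReflectanceCube

# Reflectance constants used for band inversion.  With blue=0.04 and
# red=0.08 the EVI denominator term 6*red - 7.5*blue + 1 = 1.18, and
# any EVI in (0.01, 0.95) maps to NIR within [0, 1].
_BLUE = 0.04
_RED = 0.08
_EVI_FEASIBLE = (0.01, 0.95)


@dataclass(frozen=True)
class PatchSpec:
    """Phenology of one land-cover patch (sinusoidal EVI cycle)."""

    igbp: str
    evi_base: float  # dormant-season EVI
    evi_amplitude: float  # peak minus base
    peak_doy: float  # DOY of the seasonal maximum


@dataclass(frozen=True)
class FixtureSpec:
    """Everything needed to fabricate one tile's worth of inputs.

    Defaults give a mid-latitude 50 x 50 tile over 3 years with ~25%
    clustered cloud gaps and EVI noise sigma 0.02 -- the conditions the
    recovery tests are run under.
    """

    seed: int = 0
    grid: GridGeometry = GridGeometry(
        lon0=10.0, lat0=45.0, cell_size=0.005, n_rows=50, n_cols=50
    )
    years: tuple[int, ...] = (2000, 2001, 2002)
    patches: tuple[PatchSpec, ...] = (
        PatchSpec("ENF", 0.25, 0.35, 200.0),
        PatchSpec("GRA", 0.15, 0.45, 190.0),
        PatchSpec("CRO", 0.12, 0.55, 210.0),
        PatchSpec("SAV", 0.18, 0.30, 180.0),
    )
    # Cloud model: first-order Markov chain over composites per pixel,
    # tuned so the stationary flagged fraction is gap_probability and
    # flagged composites come in runs (mean run length ~1/(1-persistence)).
    gap_probability: float = 0.25
    gap_persistence: float = 0.5
    cloud_evi_depression: float = 0.2  # clouds lower apparent EVI
    cloud_lswi_boost: float = 0.1  # and raise apparent LSWI
    noise_sigma: float = 0.02
    winter_snow_probability: float = 0.0
    # Climate (coarse 0.5-degree grid, mid-latitude seasonal cycle)
    climate_cell_size: float = 0.5
    t_mean_annual: float = 10.0  # degC
    t_seasonal_amplitude: float = 12.0
    t_peak_doy: float = 200.0
    t_daily_noise: float = 1.5
    diurnal_range: float = 8.0  # tmax - tmean ~ U(0, diurnal_range)
    sw_mean: float = 180.0  # W m-2
    sw_seasonal_amplitude: float = 100.0
    sw_daily_noise: float = 15.0
    # C4 fractions
    crop_c4_ratio_range: tuple[float, float] = (0.2, 0.8)
    natural_c4_ratio_range: tuple[float, float] = (0.0, 0.6)

    def rng(self, stream: str) -> np.random.Generator:
        # crc32 keeps the per-stream offset stable across processes
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


def _seasonal_evi(spec: FixtureSpec, patch_index: np.ndarray) -> np.ndarray:
    """Truth EVI (n_composites_total,) x grid from patch phenology."""
    n_t = len(spec.years) * N_COMPOSITES
    out = np.empty((n_t,) + spec.grid.shape)
    doys = np.array(
        [composite_start_doy(k) + 3.5 for _ in spec.years for k in range(1, N_COMPOSITES + 1)]
    )
    for i, patch in enumerate(spec.patches):
        phase = 2 * np.pi * (doys - patch.peak_doy) / 365.0
        curve = patch.evi_base + patch.evi_amplitude * (0.5 + 0.5 * np.cos(phase))
        if curve.min() < 0 or curve.max() > 1:
            raise ValueError(f"infeasible phenology for patch {patch.igbp}")
        out[:, patch_index == i] = curve[:, None]
    return out


def patch_raster(spec: FixtureSpec) -> np.ndarray:
    """Quadrant assignment of pixels to patches (patch index raster)."""
    rows, cols = spec.grid.shape
    n = len(spec.patches)
    ridx = (np.arange(rows)[:, None] * 2 // max(rows, 1))
    cidx = (np.arange(cols)[None, :] * 2 // max(cols, 1))
    return ((ridx * 2 + cidx) % n).astype(int)


def _markov_gaps(rng, n_t: int, shape: tuple[int, int], p: float, rho: float) -> np.ndarray:
    """Clustered Boolean gap sequence with stationary probability p."""
    if p <= 0:
        return np.zeros((n_t,) + shape, dtype=bool)
    if p >= 1:
        return np.ones((n_t,) + shape, dtype=bool)
    # two-state chain: P(flag->flag) = rho + (1-rho)p, P(clear->flag) = (1-rho)p
    stay = rho + (1 - rho) * p
    enter = (1 - rho) * p
    out = np.empty((n_t,) + shape, dtype=bool)
    out[0] = rng.random(shape) < p
    for t in range(1, n_t):
        prob = np.where(out[t - 1], stay, enter)
        out[t] = rng.random(shape) < prob
    return out


def _invert_reflectance(evi: np.ndarray, lswi: np.ndarray):
    """Solve the band reflectances that reproduce given EVI and LSWI."""
    evi = np.clip(evi, *_EVI_FEASIBLE)
    nir = (2.5 * _RED + evi * (6 * _RED - 7.5 * _BLUE + 1.0)) / (2.5 - evi)
    lswi = np.clip(lswi, -0.6, 0.9)
    swir = nir * (1.0 - lswi) / (1.0 + lswi)
    return (
        np.full(evi.shape, _BLUE),
        np.full(evi.shape, _RED),
        nir,
        np.clip(swir, 0.0, 1.0),
    )


def _qa_words(cloudy: np.ndarray, snowy: np.ndarray, dialect: str) -> np.ndarray:
    layout = QA_DIALECTS[dialect]
    clear_word = 0b01 << layout["aerosol_shift"]  # clear sky, low aerosol
    cloud_word = (0b01 << layout["cloud_shift"]) | (0b11 << layout["aerosol_shift"])
    words = np.where(cloudy, cloud_word, clear_word)
    return words | (snowy.astype(int) << layout["snow_bit"])


@dataclass
class ReflectanceFixture:
    cube: ReflectanceCube
    truth_evi: np.ndarray
    truth_lswi: np.ndarray
    cloudy: np.ndarray
    snowy: np.ndarray
    patch_index: np.ndarray


def generate_reflectance_cube(
    spec: FixtureSpec, dialect: str = "mod09a1_state"
) -> ReflectanceFixture:
    """Reflectance + QA cube with retained truth EVI/LSWI.

    Observed indices are truth + Gaussian noise; cloud-flagged
    composites additionally have EVI depressed and LSWI raised the way
    optically thick atmospheres bias the real indices.  Bands are then
    inverted exactly from the observed indices, so recomputing the
    indices from the bands recovers them to rounding error.
    """
    rng = spec.rng("reflectance")
    n_t = len(spec.years) * N_COMPOSITES
    patch_index = patch_raster(spec)
    truth_evi = _seasonal_evi(spec, patch_index)
    truth_lswi = np.clip(truth_evi * 0.55 - 0.05, -0.6, 0.9)

    cloudy = _markov_gaps(rng, n_t, spec.grid.shape, spec.gap_probability,
                          spec.gap_persistence)
    doys = np.array([composite_start_doy(k) + 3.5
                     for _ in spec.years for k in range(1, N_COMPOSITES + 1)])
    winter = (doys < 60) | (doys > 320)
    snowy = np.zeros_like(cloudy)
    if spec.winter_snow_probability > 0:
        snowy[winter] = rng.random((winter.sum(),) + spec.grid.shape) < \
            spec.winter_snow_probability

    evi_obs = truth_evi + rng.normal(0.0, spec.noise_sigma, truth_evi.shape) \
        if spec.noise_sigma > 0 else truth_evi.copy()
    lswi_obs = truth_lswi + rng.normal(0.0, spec.noise_sigma, truth_lswi.shape) \
        if spec.noise_sigma > 0 else truth_lswi.copy()
    evi_obs = np.where(cloudy, evi_obs - spec.cloud_evi_depression, evi_obs)
    lswi_obs = np.where(cloudy, lswi_obs + spec.cloud_lswi_boost, lswi_obs)
    lswi_obs = np.where(snowy, lswi_obs + spec.cloud_lswi_boost, lswi_obs)

    blue, red, nir, swir = _invert_reflectance(evi_obs, lswi_obs)
    qa = _qa_words(cloudy, snowy, dialect)
    calendar = [(y, k) for y in spec.years for k in range(1, N_COMPOSITES + 1)]
    cube = ReflectanceCube(blue, red, nir, swir, qa, calendar)
    return ReflectanceFixture(cube, truth_evi, truth_lswi, cloudy, snowy, patch_index)


@dataclass
class ClimateFixture:
    dswrf: dict[int, np.ndarray]  # year -> (n_days, n_lat, n_lon)
    tmax: dict[int, np.ndarray]
    tmean: dict[int, np.ndarray]
    lon: np.ndarray
    lat: np.ndarray


def generate_climate(spec: FixtureSpec) -> ClimateFixture:
    """Daily coarse-grid climate over the tile with a one-cell margin.

    Temperature follows a sinusoidal annual cycle plus daily noise and
    a weak north-south gradient; tmax >= tmean by construction.
    Shortwave flux is seasonal, nonnegative."""
    rng = spec.rng("climate")
    lon_min, lat_min, lon_max, lat_max = spec.grid.bounds()
    res = spec.climate_cell_size
    lon = np.arange(lon_min - 1.5 * res, lon_max + 1.5 * res, res)
    lat = np.arange(lat_max + 1.5 * res, lat_min - 1.5 * res, -res)
    shape = (lat.size, lon.size)
    lat_grad = (lat[:, None] - lat.mean()) * -0.5  # cooler northward

    dswrf, tmax, tmean = {}, {}, {}
    for year in spec.years:
        n_days = year_length(year)
        doy = np.arange(1, n_days + 1)
        phase = np.cos(2 * np.pi * (doy - spec.t_peak_doy) / 365.0)
        t_base = spec.t_mean_annual + spec.t_seasonal_amplitude * phase
        tm = (
            t_base[:, None, None]
            + lat_grad[None, :, :] * np.ones((1,) + shape)
            + rng.normal(0.0, spec.t_daily_noise, (n_days,) + shape)
        )
        tx = tm + rng.uniform(0.0, spec.diurnal_range, (n_days,) + shape)
        sw = np.clip(
            spec.sw_mean
            + spec.sw_seasonal_amplitude * phase[:, None, None]
            + rng.normal(0.0, spec.sw_daily_noise, (n_days,) + shape),
            0.0,
            None,
        )
        dswrf[year], tmax[year], tmean[year] = sw, tx, tm
    return ClimateFixture(dswrf, tmax, tmean, lon, lat)


@dataclass
class LandcoverFixture:
    igbp: np.ndarray  # numeric class codes on the tile grid
    crop_c4_pct: np.ndarray  # percentages on the 0.083-degree grid
    total_crop_pct: np.ndarray
    crop_grid: GridGeometry
    natural_ratio: np.ndarray  # fractions on the 1-degree grid
    natural_grid: GridGeometry
    truth_eps0: np.ndarray  # independent per-pixel effective eps0


def generate_landcover_c4(spec: FixtureSpec) -> LandcoverFixture:
    """Patchy IGBP raster + C4 fraction maps + analytic truth eps0.

    The truth eps0 re-derives the area-weighted C3/C4 mixing with
    straight-line arithmetic (hard-coded 0.42 / 0.63), independent of
    :mod:`vpmgpp.lue`, so the pipeline's map-driven lookup can be
    checked against it exactly.
    """
    rng = spec.rng("landcover")
    patch_index = patch_raster(spec)
    code_by_acr = {
        "ENF": 1, "EBF": 2, "DNF": 3, "DBF": 4, "MF": 5, "CSH": 6, "OSH": 7,
        "WSA": 8, "SAV": 9, "GRA": 10, "WET": 11, "CRO": 12, "URB": 13, "CNV": 14,
    }
    igbp = np.zeros(spec.grid.shape, dtype=int)
    for i, patch in enumerate(spec.patches):
        igbp[patch_index == i] = code_by_acr[patch.igbp]

    lon_min, lat_min, lon_max, lat_max = spec.grid.bounds()

    def covering(res):
        lon0 = np.floor(lon_min / res) * res
        lat0 = np.ceil(lat_max / res) * res
        return GridGeometry(
            lon0, lat0, res,
            int(np.ceil((lat0 - lat_min) / res)),
            int(np.ceil((lon_max - lon0) / res)),
        )

    crop_grid = covering(0.083)
    natural_grid = covering(1.0)

    # Total crop percentage per 0.083-degree cell from the class raster
    lon, lat = spec.grid.center_mesh()
    row, col = crop_grid.cell_of(lon, lat)
    cell = row * crop_grid.n_cols + col
    n_cells = crop_grid.n_rows * crop_grid.n_cols
    is_crop = np.isin(igbp, (code_by_acr["CRO"], code_by_acr["CNV"]))
    n_pix = np.bincount(cell.ravel(), minlength=n_cells).astype(float)
    n_crop = np.bincount(cell.ravel(), weights=is_crop.ravel().astype(float),
                         minlength=n_cells)
    with np.errstate(invalid="ignore"):
        total_pct = np.where(n_pix > 0, 100.0 * n_crop / np.where(n_pix > 0, n_pix, 1), 0.0)
    total_pct = total_pct.reshape(crop_grid.shape)
    lo, hi = spec.crop_c4_ratio_range
    crop_ratio_truth = rng.uniform(lo, hi, crop_grid.shape)
    c4_pct = crop_ratio_truth * total_pct

    nlo, nhi = spec.natural_c4_ratio_range
    natural_ratio = rng.uniform(nlo, nhi, natural_grid.shape)

    # Independent truth: straight-line area-weighted mixing
    truth_eps0 = np.full(spec.grid.shape, 0.42)
    c4_capable = {"SAV", "GRA", "WET", "CRO", "CNV"}
    nat_routed = {"GRA", "SAV", "WSA", "WET"}
    nrow, ncol = natural_grid.cell_of(lon, lat)
    for acr, code in code_by_acr.items():
        sel = igbp == code
        if not sel.any():
            continue
        if acr in {"CRO", "CNV"}:
            with np.errstate(invalid="ignore"):
                r = np.where(
                    total_pct[row[sel], col[sel]] > 0,
                    c4_pct[row[sel], col[sel]]
                    / np.where(total_pct[row[sel], col[sel]] > 0,
                               total_pct[row[sel], col[sel]], 1),
                    0.0,
                )
        elif acr in nat_routed and acr in c4_capable:
            r = natural_ratio[nrow[sel], ncol[sel]]
        else:
            r = np.zeros(sel.sum())
        if acr in c4_capable:
            truth_eps0[sel] = 0.42 * (1.0 - r) + 0.63 * r
    return LandcoverFixture(
        igbp, c4_pct, total_pct, crop_grid, natural_ratio, natural_grid, truth_eps0
    )


def true_gpp_oracle(evi, lswi, lswi_max, t_day, par, eps0, t_min, t_max, t_opt):
    """Independent straight-line evaluation of the GPP equations.

    Deliberately re-coded without any import from :mod:`vpmgpp.model`
    so pipeline results can be checked against it: fPAR_chl from EVI,
    temperature and water stress scalars with the same clamp rules,
    eps_g, and GPP = PAR * fPAR_chl * eps_g.
    """
    evi = np.asarray(evi, float)
    fpar = (evi - 0.1) * 1.25
    fpar = np.minimum(np.maximum(fpar, 0.0), 1.0)

    t = np.asarray(t_day, float)
    num = (t - t_max) * (t - t_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = num / (num - (t - t_opt) ** 2)
    ts = np.where((t <= t_min) | (t >= t_max), 0.0, ts)
    ts = np.minimum(np.maximum(ts, 0.0), 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ws = (1.0 + np.asarray(lswi, float)) / (1.0 + np.asarray(lswi_max, float))
    ws = np.where(np.asarray(lswi_max, float) <= -1.0, np.nan, ws)
    ws = np.minimum(np.maximum(ws, 0.0), 1.0)

    return np.asarray(par, float) * fpar * np.asarray(eps0, float) * ts * ws


def noise_free(spec: FixtureSpec) -> FixtureSpec:
    """Variant of a spec with no noise, no clouds and no snow, with
    identical phenology every year (for oracle-equivalence runs)."""
    return replace(
        spec,
        gap_probability=0.0,
        noise_sigma=0.0,
        winter_snow_probability=0.0,
        t_daily_noise=0.0,
        sw_daily_noise=0.0,
        diurnal_range=0.0,
    )
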