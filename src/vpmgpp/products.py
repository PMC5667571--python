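"""Product encoding, tiled GeoTIFF output and aggregation.

The 8-day GPP product is stored as signed 16-bit integers with a scale
factor of 0.001 (g C m-2 day-1 per count) and a -9999 nodata sentinel;
every GPP file is paired with a byte QA layer whose Boolean marks raw
(0) versus gap-filled (1) EVI.  Coarser products average the 500-m
pixels falling in each 0.05- or 0.5-degree cell over *land pixels
only*, so coastal cell values need no land-area fraction when summed
regionally.  Temporal aggregation day-weights the 46 composite means,
which makes the monthly totals an exact partition of the annual total.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .compositing import (
    N_COMPOSITES,
    all_composite_days,
    composite_month_weights,
)
from .grids import GridGeometry

GPP_SCALE = 0.001
GPP_NODATA = -9999
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def encode_gpp(gpp: np.ndarray) -> np.ndarray:
    """Quantize GPP to int16 counts of 0.001 g C m-2 day-1."""
    gpp = np.asarray(gpp, float)
    counts = np.round(gpp / GPP_SCALE)
    out = np.where(np.isfinite(gpp), counts, GPP_NODATA)
    limit = np.iinfo(np.int16).max
    if np.nanmax(np.abs(counts), initial=0) > limit:
        raise ValueError("GPP exceeds the int16 encodable range")
    return out.astype(np.int16)


def decode_gpp(encoded: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_gpp`; sentinel becomes NaN."""
    encoded = np.asarray(encoded)
    out = encoded.astype(float) * GPP_SCALE
    return np.where(encoded == GPP_NODATA, np.nan, out)


def _geo_tags(grid: GridGeometry, nodata=None):
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon0, grid.lat0, 0.0)),
    ]
    if nodata is not None:
        text = f"{nodata}\x00"
        tags.append((_TAG_GDAL_NODATA, "s", len(text), text))
    return tags


def write_gpp_tile(
    gpp: np.ndarray,
    qa: np.ndarray,
    grid: GridGeometry,
    path: str | Path,
) -> tuple[Path, Path]:
    """Write one composite's GPP + QA GeoTIFF pair.

    ``path`` is the GPP file; the QA companion gets a ``.qa.tif``
    suffix.  Scale factor and units travel in the image description.
    """
    gpp = np.asarray(gpp, float)
    qa = np.asarray(qa)
    if gpp.shape != qa.shape or gpp.shape != grid.shape:
        raise ValueError(
            f"geometry mismatch: gpp {gpp.shape}, qa {qa.shape}, grid {grid.shape}"
        )
    path = Path(path)
    qa_path = path.parent / (path.stem + ".qa.tif")
    meta = json.dumps(
        {"scale_factor": GPP_SCALE, "nodata": GPP_NODATA, "units": "g C m-2 day-1"}
    )
    tifffile.imwrite(
        path,
        encode_gpp(gpp),
        extratags=_geo_tags(grid, GPP_NODATA),
        description=meta,
    )
    tifffile.imwrite(
        qa_path,
        qa.astype(np.uint8),
        extratags=_geo_tags(grid),
        description=json.dumps({"meaning": "0=raw EVI, 1=gap-filled"}),
    )
    return path, qa_path


def read_gpp_tile(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read a GPP GeoTIFF back to float g C m-2 day-1."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    grid = GridGeometry(
        lon0=tie[3], lat0=tie[4], cell_size=scale[0],
        n_rows=data.shape[0], n_cols=data.shape[1],
    )
    return decode_gpp(data), grid


def coarse_grid_for(grid: GridGeometry, target_res: float) -> GridGeometry:
    """Coarse grid aligned to multiples of ``target_res`` covering a tile."""
    lon0 = np.floor(grid.lon0 / target_res) * target_res
    lat0 = np.ceil(grid.lat0 / target_res) * target_res
    lon_min, lat_min, lon_max, lat_max = grid.bounds()
    n_cols = int(np.ceil((lon_max - lon0) / target_res))
    n_rows = int(np.ceil((lat0 - lat_min) / target_res))
    return GridGeometry(lon0, lat0, target_res, n_rows, n_cols)


def aggregate_spatial(
    field: np.ndarray,
    grid: GridGeometry,
    target_res: float,
    land_mask: np.ndarray,
    area_weighted: bool = False,
) -> tuple[np.ndarray, GridGeometry]:
    """Average fine pixels into coarse cells, land pixels only.

    ``field`` may have leading axes before (rows, cols).  Cells without
    any land pixel (or only nodata) come back NaN.  With
    ``area_weighted`` the mean weights each pixel by cos(latitude) to
    approximate true pixel area on the lon/lat grid.
    """
    field = np.asarray(field, float)
    land_mask = np.asarray(land_mask, bool)
    if field.shape[-2:] != grid.shape or land_mask.shape != grid.shape:
        raise ValueError("field/land mask do not match the tile grid")
    if field.size == 0:
        raise ValueError("empty input field")
    coarse = coarse_grid_for(grid, target_res)
    lon, lat = grid.center_mesh()
    row, col = coarse.cell_of(lon, lat)
    cell = row * coarse.n_cols + col
    n_cells = coarse.n_rows * coarse.n_cols

    weights = np.cos(np.deg2rad(lat)) if area_weighted else np.ones(grid.shape)
    lead = field.shape[:-2]
    flat = field.reshape((-1,) + grid.shape)
    out = np.full((flat.shape[0], n_cells), np.nan)
    for i in range(flat.shape[0]):
        values = flat[i]
        use = land_mask & np.isfinite(values)
        w = np.where(use, weights, 0.0).ravel()
        num = np.bincount(cell.ravel(), weights=w * np.where(use, values, 0.0).ravel(),
                          minlength=n_cells)
        den = np.bincount(cell.ravel(), weights=w, minlength=n_cells)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out.reshape(lead + coarse.shape), coarse


def aggregate_temporal(
    composites: np.ndarray, year: int, mode: str
) -> np.ndarray:
    """Day-weighted temporal aggregation of 46 composite daily means.

    ``mode='annual'`` returns the annual total (g C m-2 yr-1);
    ``mode='monthly'`` a stack of 12 monthly totals (g C m-2 month-1),
    splitting boundary-straddling composites day by day so the twelve
    months sum exactly to the annual value.  Any missing (NaN)
    composite poisons the whole year, matching the product convention.
    """
    composites = np.asarray(composites, float)
    if composites.shape[0] != N_COMPOSITES:
        raise ValueError(f"expected {N_COMPOSITES} composites, got {composites.shape[0]}")
    days = all_composite_days(year).astype(float)
    missing = ~np.isfinite(composites)
    if mode == "annual":
        total = np.tensordot(days, np.nan_to_num(composites), axes=(0, 0))
        bad = missing.any(axis=0)
        return np.where(bad, np.nan, total) if total.ndim else (
            np.nan if bad else float(total)
        )
    if mode == "monthly":
        weights = composite_month_weights(year).astype(float)  # (46, 12)
        monthly = np.tensordot(weights, np.nan_to_num(composites), axes=(0, 0))
        bad = missing.any(axis=0)
        return np.where(bad, np.nan, monthly)
    raise ValueError(f"unknown mode {mode!r}; use 'monthly' or 'annual'")
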