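"""C3/C4 mixing of the maximum light-use efficiency.

The maximum LUE differs only by photosynthetic pathway: 0.42 g C/mol
APAR for C3 and 0.63 for C4 vegetation.  Two static fraction maps
drive the mixing: a 0.083-degree C4 *crop* fraction (C4 crop area over
total crop area per cell) applied to cropland classes, and a 1-degree
natural-C4 fraction applied to grassland, savanna, woody savanna and
wetland.  Within a map cell every 500-m pixel of the routed classes
shares the same ratio, and the effective epsilon0 is the area-weighted
average of the two pathway values.  Classes without a defined C4 value
keep the C3 epsilon0; water, snow/ice, barren and unclassified pixels
carry nodata and never produce GPP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .grids import GridGeometry

CROP_CLASSES = frozenset({"CRO", "CNV"})
NATURAL_C4_CLASSES = frozenset({"GRA", "SAV", "WSA", "WET"})


@dataclass(frozen=True)
class BiomeParameters:
    """Per-IGBP-class lookup table: epsilon0 (C3/C4) and T_min/T_max/T_opt."""

    table: pd.DataFrame  # indexed by numeric IGBP code

    def __post_init__(self) -> None:
        bad = self.table[~(
            (self.table.t_min < self.table.t_opt) & (self.table.t_opt < self.table.t_max)
        )]
        if len(bad):
            raise ValueError(f"degenerate temperature parameters for {bad.igbp.tolist()}")

    @classmethod
    def from_csv(cls, path=None) -> "BiomeParameters":
        if path is None:
            path = resources.files("vpmgpp.data") / "biome_parameters.csv"
        table = pd.read_csv(path, comment="#").set_index("code")
        return cls(table)

    @property
    def codes(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def code_of(self, acronym: str) -> int:
        match = self.table.index[self.table.igbp == acronym]
        if len(match) != 1:
            raise KeyError(f"unknown IGBP class {acronym!r}")
        return int(match[0])

    def row(self, code_or_acronym) -> pd.Series:
        if isinstance(code_or_acronym, str):
            code_or_acronym = self.code_of(code_or_acronym)
        if code_or_acronym not in self.table.index:
            raise KeyError(f"unknown IGBP class code {code_or_acronym}")
        return self.table.loc[code_or_acronym]


@dataclass
class C4FractionMaps:
    """Static C4 fraction rasters: crop at 0.083 deg, natural at 1 deg."""

    crop_ratio: np.ndarray
    crop_grid: GridGeometry
    natural_ratio: np.ndarray
    natural_grid: GridGeometry

    def __post_init__(self) -> None:
        self.crop_ratio = np.clip(np.asarray(self.crop_ratio, float), 0.0, 1.0)
        self.natural_ratio = np.clip(np.asarray(self.natural_ratio, float), 0.0, 1.0)


def crop_c4_ratio(c4_crop_pct, total_crop_pct):
    """C4-to-total crop ratio for a map cell from area percentages.

    Cells with no crop area at all get ratio 0; a C4 percentage above
    the total is clamped (with a warning) rather than rejected.
    """
    c4 = np.asarray(c4_crop_pct, float)
    total = np.asarray(total_crop_pct, float)
    if (c4 < 0).any() or (total < 0).any():
        raise ValueError("crop percentages must be nonnegative")
    if (c4 > total).any():
        warnings.warn("C4 crop percentage exceeds total crop percentage; clamping")
        c4 = np.minimum(c4, total)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, c4 / np.where(total > 0, total, 1.0), 0.0)
    return ratio if ratio.ndim else float(ratio)


def lookup_c4_ratio(
    lon: np.ndarray,
    lat: np.ndarray,
    igbp: np.ndarray,
    maps: C4FractionMaps,
    params: BiomeParameters,
) -> np.ndarray:
    """Per-pixel C4 fraction routed by land-cover class.

    Cropland classes read the crop map, natural C4 classes the
    1-degree natural map, everything else gets 0.  Pixels outside the
    relevant map get 0 with a warning.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    igbp = np.asarray(igbp)
    acr = {params.code_of(a): a for a in
           CROP_CLASSES | NATURAL_C4_CLASSES if a in set(params.table.igbp)}
    crop_codes = [c for c, a in acr.items() if a in CROP_CLASSES]
    nat_codes = [c for c, a in acr.items() if a in NATURAL_C4_CLASSES]
    ratio = np.zeros(igbp.shape, float)
    for codes, grid, field in (
        (crop_codes, maps.crop_grid, maps.crop_ratio),
        (nat_codes, maps.natural_grid, maps.natural_ratio),
    ):
        sel = np.isin(igbp, codes)
        if not sel.any():
            continue
        inside = grid.contains(lon[sel], lat[sel])
        if not inside.all():
            warnings.warn("pixels outside the C4 fraction map get ratio 0")
        row, col = grid.cell_of(lon[sel], lat[sel])
        vals = np.zeros(inside.shape)
        vals[inside] = field[row[inside], col[inside]]
        ratio[sel] = vals
    return ratio


def effective_epsilon0(igbp, c4_ratio, params: BiomeParameters) -> np.ndarray:
    """Area-weighted maximum LUE: (1-r) * eps0_C3 + r * eps0_C4.

    ``igbp`` may be numeric codes or acronyms (scalar or array);
    classes without a C4 epsilon0 return the C3 value regardless of
    ratio; unknown codes raise.
    """
    scalar = np.isscalar(igbp) or (isinstance(igbp, np.ndarray) and igbp.ndim == 0)
    codes = np.atleast_1d(
        np.asarray([params.code_of(igbp)] if isinstance(igbp, str) else igbp)
    ).astype(int)
    ratio = np.broadcast_to(np.atleast_1d(np.asarray(c4_ratio, float)), codes.shape)
    if ((ratio < 0) | (ratio > 1)).any():
        raise ValueError("c4_ratio must lie in [0, 1]")
    unknown = ~np.isin(codes, params.codes)
    if unknown.any():
        raise KeyError(f"unknown IGBP codes {np.unique(codes[unknown]).tolist()}")
    c3 = params.table.eps0_c3.reindex(codes).to_numpy()
    c4 = params.table.eps0_c4.reindex(codes).to_numpy()
    out = np.where(np.isnan(c4), c3, (1.0 - ratio) * c3 + ratio * np.nan_to_num(c4))
    return float(out[0]) if scalar else out.reshape(np.shape(igbp))


def epsilon0_map(
    igbp_raster: np.ndarray,
    grid: GridGeometry,
    maps: C4FractionMaps,
    params: BiomeParameters,
) -> np.ndarray:
    """Effective epsilon0 raster for a tile; nodata (NaN) where the
    class is not in the parameter table (water, snow, barren, ...)."""
    lon, lat = grid.center_mesh()
    igbp = np.asarray(igbp_raster)
    known = np.isin(igbp, params.codes)
    eps0 = np.full(igbp.shape, np.nan)
    if known.any():
        ratio = lookup_c4_ratio(lon[known], lat[known], igbp[known], maps, params)
        eps0[known] = effective_epsilon0(igbp[known], ratio, params)
    return eps0
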