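"""Simple equirectangular grid geometry.

Tiles and static maps are described by an origin (upper-left corner),
a cell size in degrees and a shape; pixel centers sit half a cell in
from the corner.  This is all the geometry the synthetic tiles and the
0.083-degree / 1-degree C4 fraction maps need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid anchored at its upper-left corner.

    ``lon0``/``lat0`` are the corner coordinates of the (0, 0) cell;
    latitude decreases down the rows, longitude increases across
    columns, matching north-up raster convention.
    """

    lon0: float
    lat0: float
    cell_size: float
    n_rows: int
    n_cols: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat0 - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) at pixel centers."""
        lon = np.broadcast_to(self.lon_centers(), self.shape)
        lat = np.broadcast_to(self.lat_centers()[:, None], self.shape)
        return lon, lat

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each coordinate (floor rule)."""
        col = np.floor((np.asarray(lon) - self.lon0) / self.cell_size).astype(int)
        row = np.floor((self.lat0 - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        row, col = self.cell_of(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max)."""
        return (
            self.lon0,
            self.lat0 - self.n_rows * self.cell_size,
            self.lon0 + self.n_cols * self.cell_size,
            self.lat0,
        )
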