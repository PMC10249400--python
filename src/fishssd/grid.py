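"""Grid conventions shared by every raster in the pipeline.

All rasters (concentration fields, region maps, effect-factor grids) live on
the same regular latitude/longitude grid, by default the global 0.5-degree
grid (360 rows x 720 columns). The origin is the north-west corner
(latitude +90, longitude -180); rows increase southward, columns eastward.

Cell (r, c) covers latitudes in [lat0 - res*(r+1), lat0 - res*r) and
longitudes in [lon0 + res*c, lon0 + res*(c+1)). Points exactly on the
northern (+90) or eastern (+180) edge clamp to the nearest valid cell, so
every in-range coordinate maps to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon raster geometry.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions. The global default is 360 x 720.
    resolution : float
        Cell size in decimal degrees (default 0.5).
    lat0, lon0 : float
        North-west corner of the grid.
    """

    rows: int = 360
    cols: int = 720
    resolution: float = 0.5
    lat0: float = 90.0
    lon0: float = -180.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def lat_min(self) -> float:
        return self.lat0 - self.rows * self.resolution

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.cols * self.resolution

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col) indices; vectorized.

        Out-of-extent coordinates yield -1 in both indices. Points on the
        northern/eastern boundary clamp inward.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        res = self.resolution
        lat_f = np.where(np.isnan(lat), self.lat0, lat)
        lon_f = np.where(np.isnan(lon), self.lon0, lon)
        # rows: lat in [lat0 - res*(r+1), lat0 - res*r)  =>  r = ceil((lat0-lat)/res) - 1
        row = np.ceil((self.lat0 - lat_f) / res).astype(int) - 1
        col = np.floor((lon_f - self.lon0) / res).astype(int)
        # clamp inward: covers the closed +90/+180 edges and float round-off
        # of coordinates within half an ulp of a grid boundary
        row = np.clip(row, 0, self.rows - 1)
        col = np.clip(col, 0, self.cols - 1)
        bad = (
            (lat > self.lat0)
            | (lat < self.lat_min)
            | (lon < self.lon0)
            | (lon > self.lon_max)
            | np.isnan(lat)
            | np.isnan(lon)
        )
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        if row.ndim == 0:
            return int(row), int(col)
        return row, col

    def cell_bounds(self, row: int, col: int):
        """Return (lat_south, lat_north, lon_west, lon_east) of a cell."""
        res = self.resolution
        lat_n = self.lat0 - res * row
        lon_w = self.lon0 + res * col
        return lat_n - res, lat_n, lon_w, lon_w + res

    def lat_centers(self) -> np.ndarray:
        res = self.resolution
        return self.lat0 - res * (np.arange(self.rows) + 0.5)

    def lon_centers(self) -> np.ndarray:
        res = self.resolution
        return self.lon0 + res * (np.arange(self.cols) + 0.5)
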