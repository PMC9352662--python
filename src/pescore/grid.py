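"""Global 0.5-degree grid conventions shared by every module.

The world is discretised into half-degree cells, indexed row-major from the
north-west corner.  Cells are half-open in both axes: a point with
``lon in [-180, 180)`` and ``lat in (-90, 90]`` belongs to exactly one cell,
and a longitude that falls exactly on a cell edge belongs to the cell that
starts there (eastward), a latitude on an edge to the cell extending south.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: authalic Earth radius in km (sphere of equal surface area)
EARTH_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class GridSpec:
    """The shared global raster grid: 0.5-degree cells, NW origin, row-major."""

    resolution: float = 0.5
    lon_min: float = -180.0
    lat_max: float = 90.0
    n_cols: int = 720
    n_rows: int = 360

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0 or self.resolution <= 0:
            raise ValueError("grid dimensions and resolution must be positive")
        if not np.isclose(self.n_cols * self.resolution, 360.0) or not np.isclose(
            self.n_rows * self.resolution, 180.0
        ):
            raise ValueError("grid must tile the full globe")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_of(self, lon, lat):
        """Map coordinates to flat cell indices (row-major from NW corner).

        Raises ``ValueError`` naming the offending point index when a
        coordinate is outside the world bounds.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        bad = (lon < -180.0) | (lon >= 180.0) | (lat <= -90.0) | (lat > 90.0)
        if np.any(bad):
            idx = int(np.flatnonzero(np.atleast_1d(bad))[0])
            raise ValueError(f"coordinate out of world bounds at point index {idx}")
        col = np.floor((lon - self.lon_min) / self.resolution).astype(np.int64)
        row = np.floor((self.lat_max - lat) / self.resolution).astype(np.int64)
        # lat == 90 gives row 0 by construction; lat just above a cell edge
        # belongs to the cell extending south, which floor already provides.
        row = np.clip(row, 0, self.n_rows - 1)
        out = row * self.n_cols + col
        return int(out) if out.ndim == 0 else out

    def rowcol(self, cells):
        cells = np.asarray(cells, dtype=np.int64)
        return cells // self.n_cols, cells % self.n_cols

    def cell_bounds(self, cell: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell rectangle."""
        row, col = divmod(int(cell), self.n_cols)
        x0 = self.lon_min + col * self.resolution
        y1 = self.lat_max - row * self.resolution
        return (x0, y1 - self.resolution, x0 + self.resolution, y1)

    def cell_center(self, cells):
        row, col = self.rowcol(cells)
        lon = self.lon_min + (col + 0.5) * self.resolution
        lat = self.lat_max - (row + 0.5) * self.resolution
        return lon, lat

    def row_cell_area_km2(self) -> np.ndarray:
        """Spherical (authalic) area of one cell per grid row, km^2.

        Area of a lon-lat rectangle on a sphere:
        R^2 * dlon_rad * (sin(lat_top) - sin(lat_bottom)).
        """
        res = np.deg2rad(self.resolution)
        lat_top = np.deg2rad(self.lat_max - np.arange(self.n_rows) * self.resolution)
        lat_bot = lat_top - np.deg2rad(self.resolution)
        return EARTH_RADIUS_KM**2 * res * (np.sin(lat_top) - np.sin(lat_bot))

    def cell_area_km2(self, cells) -> np.ndarray:
        row, _ = self.rowcol(cells)
        return self.row_cell_area_km2()[row]


#: module-level default: the analysis grid used throughout
WORLD_GRID = GridSpec()
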