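"""Geographic grid conventions shared by all raster layers.

All rasters in this package live on a regular lon/lat (WGS84) grid described
by a :class:`GridSpec`. Row 0 is the northernmost row, cells are half-open
boxes ``[lon_min + c*res, lon_min + (c+1)*res) x (lat_max - (r+1)*res,
lat_max - r*res]`` and values are interpreted at cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: km per degree of great-circle arc (spherical Earth, equatorial scaling).
KM_PER_DEGREE = 111.320


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid (row 0 = northernmost row).

    Parameters
    ----------
    lon_min : float
        Western edge of the grid (degrees).
    lat_max : float
        Northern edge of the grid (degrees).
    resolution : float
        Cell size in degrees (default 0.33, the assignment resolution).
    n_rows, n_cols : int
        Grid shape.
    """

    lon_min: float
    lat_max: float
    n_rows: int
    n_cols: int
    resolution: float = 0.33
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.resolution

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.n_rows * self.resolution

    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (length n_cols)."""
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (length n_rows)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        return (
            self.lon_min + (col + 0.5) * self.resolution,
            self.lat_max - (row + 0.5) * self.resolution,
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the half-open cell containing a point.

        Raises ``ValueError`` for points outside the grid extent.
        """
        col = int(np.floor((lon - self.lon_min) / self.resolution))
        row = int(np.floor((self.lat_max - lat) / self.resolution))
        # a point exactly on the northern/western edge belongs to row/col 0
        if lat == self.lat_max:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent")
        return row, col

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.lon_min - other.lon_min) <= tol
            and abs(self.lat_max - other.lat_max) <= tol
            and abs(self.resolution - other.resolution) <= tol
        )


def cell_area_km2(grid: GridSpec, row: int) -> float:
    """Approximate area (km^2) of a cell in the given row.

    Uses the small-cell approximation (res * 111.320 km)^2 * cos(latitude of
    the row's cell centers); strictly decreasing away from the equator.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} out of range [0, {grid.n_rows})")
    lat = grid.lat_max - (row + 0.5) * grid.resolution
    side = grid.resolution * KM_PER_DEGREE
    return side * side * float(np.cos(np.radians(lat)))


def cell_areas_km2(grid: GridSpec) -> np.ndarray:
    """Per-cell areas (km^2) as an (n_rows, n_cols) array."""
    lat = grid.lat_centers()
    side = grid.resolution * KM_PER_DEGREE
    col_area = side * side * np.cos(np.radians(lat))
    return np.repeat(col_area[:, None], grid.n_cols, axis=1)
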