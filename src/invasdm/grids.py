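"""Gridded single-band rasters on a geographic (WGS84) lattice.

A :class:`Grid` is a 2-D array of one environmental variable or one
prediction surface plus the georeferencing needed to place every cell:
cell-centre registration, row 0 is the northernmost row, columns increase
eastward.  Nodata is carried as NaN internally and written as -9999.

Rasters are read and written as ESRI ASCII grids (``.asc``) — a plain-text
single-band format that any GIS opens directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlignmentError, ConfigError

NODATA = -9999.0

#: WGS84 mean Earth radius in km, used for all great-circle distances.
EARTH_RADIUS_KM = 6371.0088


@dataclass
class Grid:
    """Single-band georeferenced raster.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata cells.
    origin_lon, origin_lat
        Longitude/latitude of the **centre** of the top-left (northwest)
        cell, in decimal degrees.
    cell_size
        Cell edge length in decimal degrees (square cells).
    """

    values: np.ndarray
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ConfigError("grid values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return ~np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def require_same_geometry(self, other: "Grid") -> None:
        if not self.same_geometry(other):
            raise AlignmentError(
                f"grid geometries differ: {self.shape}@({self.origin_lon},"
                f"{self.origin_lat},{self.cell_size}) vs {other.shape}@"
                f"({other.origin_lon},{other.origin_lat},{other.cell_size})"
            )

    def with_values(self, values: np.ndarray) -> "Grid":
        """New grid with the same georeferencing and different values."""
        return Grid(np.asarray(values, dtype=float), self.origin_lon,
                    self.origin_lat, self.cell_size)

    # -- coordinate transforms -------------------------------------------

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Longitude/latitude of cell centres (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + col * self.cell_size
        lat = self.origin_lat - row * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of all cell-centre coordinates, shape (rows, cols)."""
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols),
                             indexing="ij")
        return self.cell_center(rr, cc)

    def locate(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (may be out of range)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size + 0.5).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size + 0.5).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.locate(lon, lat)
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)

    # -- I/O --------------------------------------------------------------

    def to_ascii(self, path: str | Path) -> None:
        write_ascii_grid(self, path)


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (nodata -9999)."""
    path = Path(path)
    vals = np.where(grid.mask, grid.values, NODATA)
    xll = grid.origin_lon - grid.cell_size / 2.0
    yll = grid.origin_lat + grid.cell_size / 2.0 - grid.rows * grid.cell_size
    header = (
        f"ncols {grid.cols}\n"
        f"nrows {grid.rows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    cs = header["cellsize"]
    origin_lon = header["xllcorner"] + cs / 2.0
    origin_lat = header["yllcorner"] + header["nrows"] * cs - cs / 2.0
    return Grid(values, origin_lon, origin_lat, cs)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on the WGS84 mean-radius sphere.

    Inputs broadcast; degrees in, kilometres out.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
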