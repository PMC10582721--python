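"""Raster containers for elevation and interpolated phenology maps.

Grids are axis-aligned lat/lon (WGS84 decimal degree) rasters stored
row-major with row 0 at the *top* (northernmost row), matching the ESRI
ASCII grid convention used for on-disk interchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ElevationGrid", "PhenoMap", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class ElevationGrid:
    """A rectangular elevation raster in m asl on a lat/lon grid.

    Parameters
    ----------
    xll, yll
        Coordinates (deg) of the lower-left *corner* of the grid.
    cellsize
        Cell edge length in degrees (square cells).
    values
        ``(n_rows, n_cols)`` array, row 0 = northernmost row.
    nodata
        Sentinel for missing cells.
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) of the outer grid edge."""
        return (
            self.yll,
            self.yll + self.n_rows * self.cellsize,
            self.xll,
            self.xll + self.n_cols * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lat, lon) arrays of shape (n_rows, n_cols) of cell centers."""
        cs = self.cellsize
        lons = self.xll + (np.arange(self.n_cols) + 0.5) * cs
        # row 0 is the top row
        lats = self.yll + (self.n_rows - np.arange(self.n_rows) - 0.5) * cs
        lon_g, lat_g = np.meshgrid(lons, lats)
        return lat_g, lon_g

    def _index_of(self, lat: float, lon: float) -> tuple[int, int]:
        lat_min, lat_max, lon_min, lon_max = self.extent
        if not (lat_min <= lat <= lat_max and lon_min <= lon <= lon_max):
            raise ValueError(
                f"point ({lat}, {lon}) outside grid extent "
                f"lat [{lat_min}, {lat_max}], lon [{lon_min}, {lon_max}]"
            )
        cs = self.cellsize
        # Nearest-cell rule with lower-left tie break: a point exactly on a
        # cell edge belongs to the cell below/left of the edge.
        col = math.ceil((lon - self.xll) / cs) - 1
        row_from_bottom = math.ceil((lat - self.yll) / cs) - 1
        col = min(max(col, 0), self.n_cols - 1)
        row_from_bottom = min(max(row_from_bottom, 0), self.n_rows - 1)
        return self.n_rows - 1 - row_from_bottom, col

    def sample(self, lat, lon) -> np.ndarray | float:
        """Elevation of the cell containing each point (nearest-cell rule).

        Points exactly on a cell edge resolve to the lower-left cell.
        Raises ``ValueError`` for points outside the grid extent.
        """
        lat_arr = np.atleast_1d(np.asarray(lat, dtype=float))
        lon_arr = np.atleast_1d(np.asarray(lon, dtype=float))
        lat_min, lat_max, lon_min, lon_max = self.extent
        bad = (
            (lat_arr < lat_min)
            | (lat_arr > lat_max)
            | (lon_arr < lon_min)
            | (lon_arr > lon_max)
        )
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({lat_arr[i]}, {lon_arr[i]}) outside grid extent"
            )
        cs = self.cellsize
        col = np.ceil((lon_arr - self.xll) / cs).astype(int) - 1
        rfb = np.ceil((lat_arr - self.yll) / cs).astype(int) - 1
        col = np.clip(col, 0, self.n_cols - 1)
        rfb = np.clip(rfb, 0, self.n_rows - 1)
        out = self.values[self.n_rows - 1 - rfb, col]
        if np.isscalar(lat) and np.isscalar(lon):
            return float(out[0])
        return out


@dataclass
class PhenoMap:
    """Interpolated onset-of-flowering DOYs on the geometry of an ElevationGrid.

    ``mask`` is True where the cell is excluded (elevation above the mask
    threshold, nodata, or outside the domain); masked cells hold NaN.
    """

    grid: ElevationGrid
    values: np.ndarray
    mask: np.ndarray
    mask_above_m: float = 1000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.values.shape:
            raise ValueError("map shape must match grid shape")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match map shape")

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def to_frame(self):
        """Flatten to a DataFrame (row, col, lat, lon, doy, masked)."""
        import pandas as pd

        lat_g, lon_g = self.grid.cell_centers()
        rows, cols = np.indices(self.values.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "lat": lat_g.ravel(),
                "lon": lon_g.ravel(),
                "doy": self.values.ravel(),
                "masked": self.mask.ravel(),
            }
        )


def write_ascii_grid(grid: ElevationGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (.asc)."""
    path = Path(path)
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.xll!r}\n"
        f"yllcorner {grid.yll!r}\n"
        f"cellsize {grid.cellsize!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6f")


def read_ascii_grid(path: str | Path) -> ElevationGrid:
    """Read an ESRI ASCII raster (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data does not match declared dimensions")
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return ElevationGrid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        values=values,
        nodata=nodata,
    )
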