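"""Minimal geographic raster container and ESRI ASCII grid I/O.

All rasters in this package live on regular lon/lat grids (geographic
coordinates, WGS84-style sphere). A :class:`Raster` stores a 2-D array whose
row 0 is the *northernmost* row, together with the affine pieces needed to
map cells to coordinates: the lower-left corner and a square cell size in
degrees. Stacks of co-registered layers are plain dicts of Raster sharing a
grid.

The on-disk format is the ESRI ASCII grid (``.asc``), a self-describing
plain-text format that round-trips exactly at the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA_DEFAULT = -9999.0


@dataclass
class Raster:
    """A single-band raster on a regular geographic grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.
    xll, yll
        Longitude / latitude of the lower-left corner of the grid (degrees).
    cellsize
        Cell edge length in degrees (square cells).
    nodata
        Sentinel for missing cells; NaN is used internally.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = _NODATA_DEFAULT
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 first (north to south)."""
        top = self.yll + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def same_grid(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(np.asarray(values, dtype=float), self.xll, self.yll,
                      self.cellsize, self.nodata, self.crs)

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        top = self.yll + self.nrows * self.cellsize
        row = int(np.floor((top - lat) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lat}, {lon}) outside raster extent")
        return row, col

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell areas on the 6371-km sphere (latitude corrected)."""
        r = 6371.0
        lat_edges_top = np.deg2rad(self.lat_centers() + self.cellsize / 2.0)
        lat_edges_bot = np.deg2rad(self.lat_centers() - self.cellsize / 2.0)
        band = (np.sin(lat_edges_top) - np.sin(lat_edges_bot)) * r * r
        width = np.deg2rad(self.cellsize)
        per_row = band * width
        return np.repeat(per_row[:, None], self.ncols, axis=1)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = raster.nodata
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.xll:.9f}\n"
        f"yllcorner {raster.yll:.9f}\n"
        f"cellsize {raster.cellsize:.9f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.9g")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _NODATA_DEFAULT)
    vals[vals == nodata] = np.nan
    r = Raster(vals, header["xllcorner"], header["yllcorner"],
               header["cellsize"], nodata)
    if r.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape mismatch reading {path}")
    return r
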