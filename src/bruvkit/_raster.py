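"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Rows are stored bottom-up: ``data[0, 0]`` is the south-west cell. Cell
centers are the point coordinates of a cell, matching the convention used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a regular square grid in projected metres.

    Attributes
    ----------
    data : ndarray of shape (nrows, ncols)
        Cell values, row 0 at the *southern* edge.
    x0, y0 : float
        Coordinates of the south-west corner of the grid (not cell center).
    cell_size : float
        Cell edge length in metres.
    """

    data: np.ndarray
    x0: float
    y0: float
    cell_size: float
    nodata: float = field(default=_NODATA)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        ny, nx = self.data.shape
        return (self.x0, self.y0,
                self.x0 + nx * self.cell_size, self.y0 + ny * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of all cell centers (1-D each)."""
        ny, nx = self.data.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Row/col indices of the cell(s) containing point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return row, col

    def value_at(self, x, y):
        """Raster value at point(s); raises IndexError outside the grid."""
        row, col = self.index_of(x, y)
        ny, nx = self.data.shape
        if np.any(row < 0) or np.any(row >= ny) or np.any(col < 0) or np.any(col >= nx):
            raise IndexError("point outside raster extent")
        return self.data[row, col]

    def write_ascii(self, path: str | Path) -> None:
        """Write as ESRI ASCII grid (text; rows top-down per the format)."""
        ny, nx = self.data.shape
        out = np.flipud(np.where(np.isnan(self.data), self.nodata, self.data))
        header = (
            f"ncols {nx}\nnrows {ny}\n"
            f"xllcorner {self.x0!r}\nyllcorner {self.y0!r}\n"
            f"cellsize {self.cell_size!r}\nNODATA_value {self.nodata!r}\n"
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii`."""
    with open(path, encoding="utf-8") as fh:
        hdr = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[1].lstrip("-+").replace(".", "", 1).isdigit():
                fh.seek(pos)
                break
            hdr[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = hdr.get("nodata_value", _NODATA)
    data = np.flipud(data)
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        data=data,
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
        cell_size=hdr["cellsize"],
        nodata=nodata,
    )
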