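"""Minimal georeferenced raster grid.

A :class:`RasterGrid` is a rectangular 2D array of cell values on a
projected, north-up lattice with square cells.  The origin is the
upper-left corner of the upper-left cell; row indices increase southward.
Nodata is represented internally as NaN.

Rasters round-trip through the ESRI ASCII grid format (plain text), which
keeps every layer human-readable and diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    """2D value grid with square cells in a projected CRS.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks nodata.
    cell_size : float
        Cell edge length in metres.
    origin : (float, float)
        (x, y) of the upper-left corner of the grid.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-dimensional")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where nodata."""
        return np.isnan(self.values)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        x0, y0 = self.origin
        return (x0, y0 - self.nrows * self.cell_size,
                x0 + self.ncols * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-center coordinates, shape = grid shape."""
        x0, y0 = self.origin
        cs = self.cell_size
        xs = x0 + (np.arange(self.ncols) + 0.5) * cs
        ys = y0 - (np.arange(self.nrows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def index_of(self, x, y):
        """Row/col of the cell containing each point (vectorised).

        Raises ``ValueError`` for points outside the grid footprint.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - y) / self.cell_size).astype(int)
        # points exactly on the outer max edge belong to the last cell
        col = np.where((x - x0) / self.cell_size == self.ncols, self.ncols - 1, col)
        row = np.where((y0 - y) / self.cell_size == self.nrows, self.nrows - 1, row)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            raise ValueError(f"{int(np.sum(bad))} point(s) outside raster extent")
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell value at each (x, y) point."""
        row, col = self.index_of(x, y)
        return self.values[row, col]

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("shape mismatch with template grid")
        return RasterGrid(values, self.cell_size, self.origin)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.cell_size, self.origin)

    # -- I/O ---------------------------------------------------------------
    def write_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (text)."""
        vals = np.where(np.isnan(self.values), NODATA, self.values)
        x0, y0 = self.origin
        yll = y0 - self.nrows * self.cell_size
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {x0!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {NODATA!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh, ndmin=2)
        nodata = header.get("nodata_value", NODATA)
        vals = np.where(vals == nodata, np.nan, vals)
        cs = header["cellsize"]
        origin = (header["xllcorner"], header["yllcorner"] + header["nrows"] * cs)
        grid = cls(vals, cs, origin)
        if grid.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid header inconsistent with data block")
        return grid


def check_aligned(*grids: RasterGrid) -> None:
    """Raise if the grids are not co-registered (shape, origin, cell size)."""
    ref = grids[0]
    for g in grids[1:]:
        if (g.shape != ref.shape or g.cell_size != ref.cell_size
                or not np.allclose(g.origin, ref.origin)):
            raise ValueError("rasters are not co-registered")
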