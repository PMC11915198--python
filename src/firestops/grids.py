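"""Minimal georeferenced raster container used by every pipeline stage.

All rasters live in a projected equal-area frame (meters, x east / y north),
row-major with the origin at the top-left corner, mirroring the convention of
the usual geospatial stacks. Layers of different native resolution (30 m tree
cover next to 345 m land cover) share the same frame but keep their own pixel
size; point lookups are nearest-cell at native resolution, never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterGrid"]


@dataclass
class RasterGrid:
    """A single-band raster on a projected planar grid.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Cell values, row 0 at the top (largest y).
    pixel_size : float
        Cell edge length in meters.
    origin : (float, float)
        (x, y) of the *top-left corner* of cell (0, 0), in meters.
    crs : str
        Free-form identifier of the projected frame. The synthetic world uses
        a local planar equal-area frame labelled ``"local-planar"``.
    """

    data: np.ndarray
    pixel_size: float = 300.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local-planar"
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"RasterGrid expects a 2-D array, got shape {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_center(self, row, col):
        """(x, y) of the center of cell (row, col); accepts arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def cell_index(self, x, y):
        """(row, col) of the cell containing point (x, y).

        A point exactly on a cell edge belongs to the cell with the lower
        index along that axis being entered, i.e. ``floor`` on the fractional
        offset: x on a vertical edge goes to the cell starting at that edge.
        This is the deterministic tie-break the window/ellipse lookups rely on.
        """
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.pixel_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def in_bounds(self, row, col):
        r, c = np.asarray(row), np.asarray(col)
        nr, nc = self.shape
        return (r >= 0) & (r < nr) & (c >= 0) & (c < nc)

    def sample(self, x, y):
        """Nearest-cell values at points (x, y); NaN outside the raster."""
        row, col = self.cell_index(x, y)
        ok = self.in_bounds(row, col)
        out = np.full(np.shape(row), np.nan, dtype=float)
        out[ok] = self.data[row[ok], col[ok]].astype(float)
        return out

    def like(self, data: np.ndarray) -> "RasterGrid":
        """A new grid sharing this georeference with different values."""
        return replace(self, data=np.asarray(data))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        nr, nc = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nr * self.pixel_size, x0 + nc * self.pixel_size, y0)

    def covers(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        """True if this raster shares the CRS of ``other`` and spatially
        covers it (coarse layers may overhang the domain by a partial cell)."""
        if self.crs != other.crs:
            return False
        xmin, ymin, xmax, ymax = self.bounds
        oxmin, oymin, oxmax, oymax = other.bounds
        return (
            xmin <= oxmin + tol and ymin <= oymin + tol
            and xmax >= oxmax - tol and ymax >= oymax - tol
        )
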