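"""Plain-text single-band raster grids.

A minimal gridded-raster container used throughout the package for land class,
elevation, roads, population, travel time and probability surfaces.

Conventions
-----------
* Row-major storage, row 0 at the **north-west** corner.
* ``cell_size`` in metres; cells are square.
* World coordinates are metres from the north-west corner of the grid:
  ``x = (col + 0.5) * cell_size`` (eastward),
  ``y = (row + 0.5) * cell_size`` (southward), i.e. coordinates refer to cell
  centres and 0-based indices.
* Nodata is NaN in memory and the literal token ``nan`` on disk.

On-disk format (``.asc``): a small ASCII header followed by ``nrows`` rows of
whitespace-separated values::

    ncols 4
    nrows 3
    cellsize 1000.0
    1.0 2.0 3.0 4.0
    ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "assert_coregistered"]


@dataclass
class Raster:
    """A single-band grid with square cells and NaN nodata."""

    data: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width_m, height_m) of the grid."""
        nrows, ncols = self.data.shape
        return ncols * self.cell_size, nrows * self.cell_size

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing world point (x, y).

        Raises ``ValueError`` when the point falls outside the grid.
        """
        width, height = self.extent
        if not (0 <= x < width and 0 <= y < height):
            raise ValueError(
                f"point ({x}, {y}) outside raster extent {width} x {height} m"
            )
        return int(y // self.cell_size), int(x // self.cell_size)

    def coords_of(self, row: int, col: int) -> tuple[float, float]:
        """World coordinates of the centre of cell (row, col)."""
        return (col + 0.5) * self.cell_size, (row + 0.5) * self.cell_size

    def value_at(self, x: float, y: float) -> float:
        """Nearest-cell value at world point (x, y); NaN where nodata."""
        r, c = self.index_of(x, y)
        return float(self.data[r, c])

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=float), self.cell_size)

    # -- I/O ---------------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        nrows, ncols = self.data.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"cellsize {self.cell_size:.17g}\n")
            for row in self.data:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        with open(path) as fh:
            header: dict[str, str] = {}
            for _ in range(3):
                key, val = fh.readline().split()
                header[key.lower()] = val
            data = np.loadtxt(fh, dtype=float, ndmin=2)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        if data.shape != (nrows, ncols):
            raise ValueError(
                f"grid body {data.shape} does not match header ({nrows}, {ncols})"
            )
        return cls(data, float(header["cellsize"]))


def assert_coregistered(*rasters: Raster) -> None:
    """Raise ``ValueError`` unless all rasters share shape and cell size."""
    ref = rasters[0]
    for r in rasters[1:]:
        if r.shape != ref.shape or r.cell_size != ref.cell_size:
            raise ValueError(
                f"rasters not co-registered: {r.shape}@{r.cell_size} vs "
                f"{ref.shape}@{ref.cell_size}"
            )
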