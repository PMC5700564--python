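"""Single-band covariate rasters in projected meters.

Row 0 is the top (northernmost) row; x grows east, y grows north; cell
centers sit at half-cell offsets from the grid edges.  I/O is the ESRI
ASCII grid format, which is plain text and matches the projected fix
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass
class CovariateRaster:
    x_origin: float      # west edge, meters
    y_origin: float      # north (top) edge, meters
    cell_size: float     # meters, square cells
    values: np.ndarray   # 2D, row 0 at top
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise DataError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("raster values must be a 2D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def y_south(self) -> float:
        return self.y_origin - self.n_rows * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing (x, y); raises if outside."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise DataError(f"point ({x:g}, {y:g}) outside raster extent")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_origin <= x < self.x_origin + self.n_cols * self.cell_size
            and self.y_south < y <= self.y_origin
        )

    def value_at(self, x: float, y: float) -> float:
        """Cell value at a point; NaN when the cell holds the no-data code."""
        row, col = self.cell_of(x, y)
        v = self.values[row, col]
        return float("nan") if v == self.nodata else float(v)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid-free center coordinates: (xs[n_cols], ys[n_rows])."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys


def read_ascii_grid(path) -> CovariateRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise DataError(f"ASCII grid missing header field {key}")
    values = np.loadtxt(lines[data_start:], dtype=float)
    values = np.atleast_2d(values)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise DataError(
            f"grid body shape {values.shape} does not match header ({n_rows}, {n_cols})"
        )
    cell = header["cellsize"]
    return CovariateRaster(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: CovariateRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {float(raster.x_origin):.10g}\n")
        fh.write(f"yllcorner {float(raster.y_south):.10g}\n")
        fh.write(f"cellsize {float(raster.cell_size):.10g}\n")
        fh.write(f"NODATA_value {float(raster.nodata):.10g}\n")
        np.savetxt(fh, raster.values, fmt="%.6g")
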