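"""Minimal planar raster container with ESRI ASCII grid I/O.

Grids live on an abstract equal-area Cartesian plane (cell size in km).
Nodata is represented as NaN in memory and written through the
``NODATA_value`` header bit-exactly on round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band grid: row 0 is the top (north) row, as in ASCII grids.

    Parameters
    ----------
    data
        2-D float array; NaN marks nodata.
    cell_size
        Edge length of a (square) cell, in km.
    xll, yll
        Coordinates of the lower-left corner of the grid.
    crs_tag
        Free-form tag for the coordinate reference (synthetic landscapes use
        ``"synthetic-equal-area"``).
    """

    data: np.ndarray
    cell_size: float = 1.0
    xll: float = 0.0
    yll: float = 0.0
    crs_tag: str = "synthetic-equal-area"
    nodata: float = field(default=DEFAULT_NODATA, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return np.isfinite(self.data)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped like data."""
        nrows, ncols = self.data.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def same_geometry(self, other: "Raster", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.xll - other.xll) <= atol
            and abs(self.yll - other.yll) <= atol
        )

    def copy_with(self, data: np.ndarray) -> "Raster":
        if np.shape(data) != self.shape:
            raise ValueError("replacement data shape mismatch")
        return Raster(np.asarray(data, dtype=float), self.cell_size, self.xll,
                      self.yll, self.crs_tag, self.nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (plain text, GDAL 'AAIGrid' compatible)."""
    nrows, ncols = raster.shape
    out = raster.data.copy()
    out[~np.isfinite(out)] = raster.nodata
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(raster.xll)!r}\n"
        f"yllcorner {float(raster.yll)!r}\n"
        f"cellsize {float(raster.cell_size)!r}\n"
        f"NODATA_value {float(raster.nodata)!r}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows, dtype=float)
    if "ncols" in header and data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    data[data == nodata] = np.nan
    return Raster(
        data,
        cell_size=header.get("cellsize", 1.0),
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        nodata=nodata,
    )
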