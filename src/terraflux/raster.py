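"""Gridded elevation data and raster file I/O.

The package works on projected coordinates in metres with the raster origin at
the *lower-left* corner of the grid.  Internally values are stored as a 2-D
float array with row 0 at the *top* (northernmost) edge, the usual raster
convention, so ``values[0, 0]`` is the north-west cell.  Missing cells are NaN.

Two plain-raster formats are supported: ESRI ASCII grid (text) and GeoTIFF
(via tifffile, writing the ModelPixelScale / ModelTiepoint GeoTIFF tags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ElevationRaster", "read_raster", "write_raster"]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass
class ElevationRaster:
    """A rectangular grid of elevation (or any scalar field) in metres.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Cell values, row 0 at the northern edge; NaN marks missing cells.
    cell_size : float
        Edge length of the square cells (m).
    origin : (float, float)
        Projected (x, y) of the lower-left corner of the grid (m).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    # ------------------------------------------------------------------ shape
    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid edges."""
        x0, y0 = self.origin
        return (x0, x0 + self.nx * self.cell_size, y0, y0 + self.ny * self.cell_size)

    # -------------------------------------------------------------- indexing
    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Return the (row, col) of the cell containing projected point (x, y).

        Points on the upper x/y edge are assigned to the last cell so that
        positions laid out on a closed [0, extent] lattice stay in bounds.
        """
        xmin, xmax, ymin, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise IndexError(
                f"position ({x}, {y}) outside raster extent "
                f"[{xmin}, {xmax}] x [{ymin}, {ymax}]"
            )
        col = min(int((x - xmin) / self.cell_size), self.nx - 1)
        row_from_bottom = min(int((y - ymin) / self.cell_size), self.ny - 1)
        return self.ny - 1 - row_from_bottom, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.index_of(x, y)
        return float(self.values[r, c])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x (nx,) and y (ny,) coordinates of cell centers; y descending like rows."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.ny)[::-1] + 0.5) * self.cell_size
        return xs, ys

    def copy(self, values: np.ndarray | None = None) -> "ElevationRaster":
        return ElevationRaster(
            self.values.copy() if values is None else values,
            self.cell_size,
            self.origin,
        )


# --------------------------------------------------------------------- ASCII
def _write_esri_ascii(raster: ElevationRaster, path: Path, nodata: float = -9999.0) -> None:
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = nodata
    header = (
        f"ncols {raster.nx}\n"
        f"nrows {raster.ny}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {nodata:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6f")


def _read_esri_ascii(path: Path) -> ElevationRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals[vals == nodata] = np.nan
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return ElevationRaster(vals, header["cellsize"], origin)


# -------------------------------------------------------------------- GeoTIFF
def _write_geotiff(raster: ElevationRaster, path: Path) -> None:
    import tifffile

    cs = raster.cell_size
    x0, y0 = raster.origin
    # tie the (0, 0) pixel corner to the upper-left map coordinate
    top = y0 + raster.ny * cs
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, top, 0.0)),
    ]
    tifffile.imwrite(path, raster.values.astype(np.float32), extratags=extratags)


def _read_geotiff(path: Path) -> ElevationRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value if _MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_MODEL_TIEPOINT].value if _MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
    cs = float(scale[0])
    x0 = float(tie[3])
    top = float(tie[4])
    ny = vals.shape[0]
    return ElevationRaster(vals, cs, (x0, top - ny * cs))


def write_raster(raster: ElevationRaster, path: str | Path) -> Path:
    """Write to ESRI ASCII (.asc/.txt) or GeoTIFF (.tif/.tiff) by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt", ".grd"}:
        _write_esri_ascii(raster, path)
    elif suffix in {".tif", ".tiff"}:
        _write_geotiff(raster, path)
    else:
        raise ValueError(f"unsupported raster extension {suffix!r}")
    return path


def read_raster(path: str | Path) -> ElevationRaster:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt", ".grd"}:
        return _read_esri_ascii(path)
    if suffix in {".tif", ".tiff"}:
        return _read_geotiff(path)
    raise ValueError(f"unsupported raster extension {suffix!r}")
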