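"""Multi-scale DEM processing ("mixed scaling") and terrain attributes.

The pyramid scheme: the base DEM is progressively smoothed and subsampled
(aggregated by a factor of two per level, plus a final level matched to the
field-sampling resolution), terrain attributes are computed on each level's
grid, and the attribute rasters are then disaggregated (nearest-neighbour
replicated) back to the base resolution.  The neighbourhood a 3x3 attribute
window covers therefore grows with the level, which is how scale enters the
analysis.

Six attributes are computed per level:

========  =============================================================
mALT      local mean elevation, 3x3 moving-window mean (m)
SD        moving-window standard deviation of elevation (m)
TPI       topographic position index: center elevation minus the mean of
          the window *excluding* the center (m); ridges > 0, dips < 0
Sl        slope angle from Horn's 3x3 finite differences (degrees)
North     cosine of the downslope aspect (aspect clockwise from north)
East      sine of the downslope aspect
========  =============================================================

Flat cells (zero gradient) get North = East = 0 by convention, so
North**2 + East**2 == 1 exactly where Sl > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import ElevationRaster

__all__ = [
    "ATTRIBUTE_NAMES",
    "PYRAMID_RESOLUTIONS",
    "TerrainAttributeStack",
    "aggregate_dem",
    "smooth_dem",
    "compute_attributes",
    "disaggregate",
    "build_pyramid",
    "extract_at_positions",
]

ATTRIBUTE_NAMES = ("mALT", "SD", "TPI", "Sl", "North", "East")

#: native cell sizes (m) of pyramid levels 1-7 for a 0.2 m base DEM
PYRAMID_RESOLUTIONS = (0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 10.0)


# ----------------------------------------------------------------- windowing
def _window_sum_count(values: np.ndarray, width: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Windowed sum over finite cells and the finite-cell count.

    mode='renormalize' treats cells beyond the edge as missing (kernel is
    renormalized over the available cells); mode='wrap' uses periodic
    boundaries (useful for exact zero-mean TPI checks).
    """
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    kernel_mode = "constant" if mode == "renormalize" else "wrap"
    ksum = ndimage.uniform_filter(filled, size=width, mode=kernel_mode, cval=0.0) * width**2
    kcnt = ndimage.uniform_filter(finite.astype(float), size=width, mode=kernel_mode, cval=0.0) * width**2
    return ksum, np.rint(kcnt)


def _window_mean(values: np.ndarray, width: int, mode: str) -> np.ndarray:
    s, c = _window_sum_count(values, width, mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / c
    out[c == 0] = np.nan
    return out


# -------------------------------------------------------------- aggregation
def aggregate_dem(dem: ElevationRaster, factor: int) -> ElevationRaster:
    """Block-mean aggregation (box blur + subsample) by an integer factor.

    Ragged edges are padded with missing cells at the south/east margins, so
    the top-left (north-west) corner of the output grid coincides with the
    input's.  Blocks whose cells are all missing stay missing.
    """
    if int(factor) != factor or factor < 2:
        raise ValueError(f"aggregation factor must be an integer >= 2, got {factor}")
    factor = int(factor)
    if min(dem.ny, dem.nx) < factor:
        raise ValueError("grid smaller than the aggregation factor")
    ny_out = math.ceil(dem.ny / factor)
    nx_out = math.ceil(dem.nx / factor)
    padded = np.full((ny_out * factor, nx_out * factor), np.nan)
    padded[: dem.ny, : dem.nx] = dem.values
    blocks = padded.reshape(ny_out, factor, nx_out, factor)
    finite = np.isfinite(blocks)
    cnt = finite.sum(axis=(1, 3))
    s = np.where(finite, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / cnt
    out[cnt == 0] = np.nan
    cs = dem.cell_size * factor
    x0 = dem.origin[0]
    top = dem.origin[1] + dem.ny * dem.cell_size
    return ElevationRaster(out, cs, (x0, top - ny_out * cs))


def smooth_dem(dem: ElevationRaster, kernel: str = "box", width_cells: int = 3) -> ElevationRaster:
    """Moving-window smoothing without subsampling.

    kernel='box' is a renormalized moving mean; kernel='gaussian' a
    Gaussian-weighted mean with sigma = width_cells / 4.  Edge windows are
    renormalized over the available cells.  width_cells must be odd
    (width 1 is the identity).
    """
    if width_cells % 2 == 0:
        raise ValueError(f"window width must be odd, got {width_cells}")
    if width_cells == 1:
        return dem.copy()
    if kernel == "box":
        return dem.copy(values=_window_mean(dem.values, width_cells, "renormalize"))
    if kernel == "gaussian":
        sigma = width_cells / 4.0
        finite = np.isfinite(dem.values)
        filled = np.where(finite, dem.values, 0.0)
        num = ndimage.gaussian_filter(filled, sigma, mode="constant", cval=0.0)
        den = ndimage.gaussian_filter(finite.astype(float), sigma, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[den == 0] = np.nan
        out[~finite] = np.nan
        return dem.copy(values=out)
    raise ValueError(f"unknown kernel {kernel!r}")


def disaggregate(raster: ElevationRaster, target_cell_size: float) -> ElevationRaster:
    """Nearest-neighbour replication down to a finer grid; values unchanged."""
    ratio = raster.cell_size / target_cell_size
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"cell size {raster.cell_size} is not an integer multiple of {target_cell_size}"
        )
    ratio = int(round(ratio))
    out = np.repeat(np.repeat(raster.values, ratio, axis=0), ratio, axis=1)
    x0 = raster.origin[0]
    top = raster.origin[1] + raster.ny * raster.cell_size
    return ElevationRaster(out, target_cell_size, (x0, top - out.shape[0] * target_cell_size))


# -------------------------------------------------------------- attributes
def _horn_gradient(values: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """(dz/dx eastward, dz/dy northward) by Horn's 3x3 weights; edges replicate."""
    wx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float) / (8.0 * cell_size)
    # row 0 is the northern edge, so the northward derivative takes top minus bottom
    wy = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], float) / (8.0 * cell_size)
    dzdx = ndimage.correlate(values, wx, mode="nearest")
    dzdy = ndimage.correlate(values, wy, mode="nearest")
    return dzdx, dzdy


def compute_attributes(
    dem: ElevationRaster, window_cells: int = 3, boundary: str = "renormalize"
) -> dict[str, ElevationRaster]:
    """Compute the six terrain attributes on the DEM's own grid.

    mALT/SD/TPI use a ``window_cells`` x ``window_cells`` moving window;
    slope and aspect always use Horn's 3x3 stencil.  ``boundary`` controls the
    window edge rule ('renormalize' or periodic 'wrap').
    """
    if window_cells % 2 == 0 or window_cells < 3:
        raise ValueError(f"window must be odd and >= 3, got {window_cells}")
    if min(dem.ny, dem.nx) < window_cells:
        raise ValueError(
            f"raster {dem.ny}x{dem.nx} smaller than the {window_cells}-cell window"
        )
    z = dem.values
    finite = np.isfinite(z)
    # center on the global mean: shift-invariant moments, and the windowed
    # variance avoids catastrophic cancellation on near-constant rasters
    shift = np.nanmean(z) if finite.any() else 0.0
    zs = z - shift

    s, c = _window_sum_count(zs, window_cells, boundary)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_s = s / c
    malt = mean_s + shift
    malt[c == 0] = np.nan

    s2, _ = _window_sum_count(zs**2, window_cells, boundary)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = s2 / c - mean_s**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd[c == 0] = np.nan

    # neighbourhood mean excluding the center cell
    zc = np.where(finite, zs, 0.0)
    cnt_excl = c - finite
    with np.errstate(invalid="ignore", divide="ignore"):
        neigh = (s - zc) / cnt_excl
    tpi = zs - neigh
    tpi[(cnt_excl == 0) | ~finite] = np.nan

    dzdx, dzdy = _horn_gradient(z, dem.cell_size)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore", divide="ignore"):
        north = np.where(grad > 0, -dzdy / grad, 0.0)
        east = np.where(grad > 0, -dzdx / grad, 0.0)
    north[~np.isfinite(slope)] = np.nan
    east[~np.isfinite(slope)] = np.nan

    make = lambda a: ElevationRaster(a, dem.cell_size, dem.origin)
    return {
        "mALT": make(malt),
        "SD": make(sd),
        "TPI": make(tpi),
        "Sl": make(slope),
        "North": make(north),
        "East": make(east),
    }


# ------------------------------------------------------------------ pyramid
@dataclass
class TerrainAttributeStack:
    """Attribute rasters per pyramid level, all on the base grid.

    ``levels[L][name]`` is an ElevationRaster at base resolution holding the
    level-L attribute; ``native_resolution[L]`` is the cell size (m) the
    attribute was computed at before disaggregation.
    """

    base: ElevationRaster
    levels: dict[int, dict[str, ElevationRaster]] = field(default_factory=dict)
    native_resolution: dict[int, float] = field(default_factory=dict)
    kernel_tag: str = "box"

    @property
    def level_ids(self) -> list[int]:
        return sorted(self.levels)


def _to_base_grid(raster: ElevationRaster, base: ElevationRaster) -> ElevationRaster:
    fine = disaggregate(raster, base.cell_size)
    vals = fine.values[: base.ny, : base.nx]
    return ElevationRaster(vals, base.cell_size, base.origin)


def build_pyramid(
    dem0: ElevationRaster,
    max_level: int = 7,
    kernel: str = "box",
    window_cells: int = 3,
    campaign_resolution: float = 10.0,
) -> TerrainAttributeStack:
    """Run the full mixed-scaling pipeline on a base DEM.

    Levels 2..6 halve the resolution of the previous level; the final level
    (7 by default) is aggregated directly from the base DEM to the
    field-campaign resolution (10 m).  Attributes are computed on each
    level's own grid, then replicated back onto the base grid.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    stack = TerrainAttributeStack(base=dem0, kernel_tag=kernel)
    dem_l = dem0
    for level in range(1, max_level + 1):
        if level == 1:
            dem_here = dem0
        elif level <= 6:
            if kernel == "gaussian":
                dem_l = aggregate_dem(smooth_dem(dem_l, "gaussian", 3), 2)
            else:
                dem_l = aggregate_dem(dem_l, 2)
            dem_here = dem_l
        else:
            factor = int(round(campaign_resolution / dem0.cell_size))
            if factor < 2:
                raise ValueError("campaign resolution must be coarser than the base DEM")
            dem_here = aggregate_dem(dem0, factor)
        if min(dem_here.ny, dem_here.nx) < window_cells:
            raise ValueError(
                f"DEM extent too small for pyramid level {level} "
                f"({dem_here.ny}x{dem_here.nx} cells at {dem_here.cell_size} m)"
            )
        attrs = compute_attributes(dem_here, window_cells)
        stack.levels[level] = {k: _to_base_grid(v, dem0) for k, v in attrs.items()}
        stack.native_resolution[level] = dem_here.cell_size
    return stack


def extract_at_positions(
    stack: TerrainAttributeStack,
    positions: pd.DataFrame,
    levels: list[int] | None = None,
) -> pd.DataFrame:
    """Pick attribute values at point positions from the base-resolution stack.

    ``positions`` needs columns position_id, x, y.  Returns one row per
    position with columns like ``TPI_L3`` for each attribute x level.
    """
    levels = stack.level_ids if levels is None else levels
    out = positions[["position_id", "x", "y"]].copy().reset_index(drop=True)
    base = stack.base
    rows_cols = [base.index_of(x, y) for x, y in zip(out["x"], out["y"])]
    rr = np.array([rc[0] for rc in rows_cols])
    cc = np.array([rc[1] for rc in rows_cols])
    for level in levels:
        if level not in stack.levels:
            raise KeyError(f"pyramid level {level} not present in stack")
        for name in ATTRIBUTE_NAMES:
            out[f"{name}_L{level}"] = stack.levels[level][name].values[rr, cc]
    return out
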