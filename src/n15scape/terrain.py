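"""Terrain derivatives from a DEM.

Implements the layers used as model predictors: circular mean filtering,
slope (tan beta), multiple-flow-direction (MFD) contributing area, the
topographic wetness index TWI = ln(a / tan beta), the topographic position
index (TPI) over an annular neighbourhood, and a five-class landform map
(ridge / slope / plain / drainage / valley) from standardised TPI.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .raster import RasterGrid

logger = logging.getLogger(__name__)

# landform class codes
RIDGE, SLOPE, PLAIN, DRAINAGE, VALLEY = 1, 2, 3, 4, 5
LANDFORM_LEGEND = {RIDGE: "ridge", SLOPE: "slope", PLAIN: "plain",
                   DRAINAGE: "drainage", VALLEY: "valley"}
LANDFORM_NAMES = tuple(LANDFORM_LEGEND.values())


@dataclass
class LandformRaster:
    """Categorical landform grid plus its legend."""

    grid: RasterGrid
    legend: dict[int, str] = field(default_factory=lambda: dict(LANDFORM_LEGEND))

    def names(self) -> np.ndarray:
        """Object array of class names ('' where nodata)."""
        out = np.full(self.grid.shape, "", dtype=object)
        for code, name in self.legend.items():
            out[self.grid.values == code] = name
        return out


def _disk_kernel(radius_cells: int) -> np.ndarray:
    r = int(radius_cells)
    ij = np.arange(-r, r + 1)
    di, dj = np.meshgrid(ij, ij, indexing="ij")
    return (np.hypot(di, dj) <= r + 1e-12).astype(float)


def _focal_mean(values: np.ndarray, kernel: np.ndarray, use_fft: bool = False) -> np.ndarray:
    """Kernel-weighted mean ignoring NaN; window clipped at edges."""
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    if use_fft:
        total = signal.fftconvolve(filled, kernel, mode="same")
        count = signal.fftconvolve(valid.astype(float), kernel, mode="same")
    else:
        total = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
        count = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(count > 0.5, total / np.maximum(count, 1e-300), np.nan)
    out[~valid] = np.nan
    return out


def mean_filter_circular(grid: RasterGrid, radius_cells: int) -> RasterGrid:
    """Mean over all cells whose centre lies within ``radius_cells`` cells.

    Edge windows are clipped to the grid; nodata cells are excluded from
    the mean and stay nodata in the output.
    """
    if radius_cells < 0:
        raise ValueError("radius must be non-negative")
    if radius_cells == 0:
        return grid.copy()
    kernel = _disk_kernel(radius_cells)
    use_fft = kernel.size > 1500  # large windows: FFT convolution
    return grid.like(_focal_mean(grid.values, kernel, use_fft=use_fft))


def slope(dem: RasterGrid) -> RasterGrid:
    """Slope as tan(beta) from central differences on cell centres.

    Interior cells use the Zevenbergen-Thorne central-difference stencil;
    border cells fall back to one-sided differences.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3 for slope")
    # rows run north->south, so -gradient along axis 0 is dz/dy
    gy, gx = np.gradient(dem.values, dem.cell_size)
    return dem.like(np.hypot(gx, gy))


def _mfd_accumulate(z: np.ndarray, order: np.ndarray, cell_size: float,
                    exponent: float) -> np.ndarray:
    """Propagate contributing area in descending-elevation order."""
    nrows, ncols = z.shape
    acc = np.full(z.size, cell_size * cell_size)
    zf = z.ravel()
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    dist = [cell_size * math.sqrt(di * di + dj * dj) for di, dj in offs]
    for idx in order:
        i, j = divmod(int(idx), ncols)
        zc = zf[idx]
        wsum = 0.0
        ws = []
        for (di, dj), d in zip(offs, dist):
            ii, jj = i + di, j + dj
            if 0 <= ii < nrows and 0 <= jj < ncols:
                zn = z[ii, jj]
                if zn < zc:
                    w = ((zc - zn) / d) ** exponent
                    ws.append((ii * ncols + jj, w))
                    wsum += w
        if wsum > 0.0:
            a = acc[idx]
            for nidx, w in ws:
                acc[nidx] += a * w / wsum
    return acc.reshape(z.shape)


try:  # optional JIT of the hot loop; identical semantics
    from numba import njit as _njit

    @_njit(cache=False)
    def _mfd_accumulate_nb(z, order, cell_size, exponent):  # pragma: no cover
        nrows, ncols = z.shape
        acc = np.full(nrows * ncols, cell_size * cell_size)
        zf = z.ravel()
        nidx = np.empty(8, dtype=np.int64)
        wts = np.empty(8)
        for oi in range(order.size):
            idx = order[oi]
            i = idx // ncols
            j = idx - i * ncols
            zc = zf[idx]
            wsum = 0.0
            nn = 0
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    if di == 0 and dj == 0:
                        continue
                    ii = i + di
                    jj = j + dj
                    if 0 <= ii < nrows and 0 <= jj < ncols:
                        zn = z[ii, jj]
                        if zn < zc:
                            d = cell_size * math.sqrt(di * di + dj * dj)
                            w = ((zc - zn) / d) ** exponent
                            nidx[nn] = ii * ncols + jj
                            wts[nn] = w
                            wsum += w
                            nn += 1
            if wsum > 0.0:
                a = acc[idx]
                for t in range(nn):
                    acc[nidx[t]] += a * wts[t] / wsum
        return acc.reshape(nrows, ncols)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def fill_pits(dem: RasterGrid) -> RasterGrid:
    """Priority-flood depression filling (optional pre-step for routing).

    Raises every cell to the lowest spill elevation reachable from the
    grid boundary, leaving drained cells untouched.
    """
    import heapq

    z = dem.values.copy()
    nrows, ncols = z.shape
    filled = np.full_like(z, np.inf)
    heap = []
    for i in range(nrows):
        for j in (0, ncols - 1):
            heapq.heappush(heap, (z[i, j], i, j))
            filled[i, j] = z[i, j]
    for j in range(1, ncols - 1):
        for i in (0, nrows - 1):
            heapq.heappush(heap, (z[i, j], i, j))
            filled[i, j] = z[i, j]
    while heap:
        level, i, j = heapq.heappop(heap)
        if level > filled[i, j]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if (di or dj) and 0 <= ii < nrows and 0 <= jj < ncols:
                    cand = max(z[ii, jj], level)
                    if cand < filled[ii, jj]:
                        filled[ii, jj] = cand
                        heapq.heappush(heap, (cand, ii, jj))
    return dem.like(filled)


def mfd_flow_accumulation(dem: RasterGrid, exponent: float = 1.1) -> RasterGrid:
    """Multiple-flow-direction contributing area (m^2).

    Each cell starts with its own area and, processed in strictly
    descending elevation order (ties broken by flat cell index), passes its
    accumulated area to every lower 8-neighbour with weight proportional to
    (slope towards that neighbour) ** exponent.  Flats and pits keep their
    accumulation.
    """
    if np.any(dem.mask):
        raise ValueError("MFD requires a DEM without nodata holes")
    z = dem.values
    flat = np.arange(z.size)
    order = np.lexsort((flat, -z.ravel()))  # descending z, ties by index
    if _HAVE_NUMBA:
        acc = _mfd_accumulate_nb(z, order.astype(np.int64), float(dem.cell_size),
                                 float(exponent))
    else:
        acc = _mfd_accumulate(z, order, float(dem.cell_size), float(exponent))
    return dem.like(acc)


def twi(accum: RasterGrid, slope_grid: RasterGrid, *, eps: float = 0.001,
        smooth_radius_cells: int = 4) -> RasterGrid:
    """Topographic wetness index ln(a / tan beta), mean-filtered.

    ``a`` is the specific catchment area: accumulation divided by the cell
    size (contributing area per unit contour length).  Zero slopes are
    floored at ``eps`` to keep the index finite.  The raw index is smoothed
    with a circular mean filter (default four-cell radius).
    """
    a = accum.values / accum.cell_size
    if np.nanmin(a) <= 0:
        raise ValueError("non-positive flow accumulation (conservation violated)")
    raw = np.log(a / np.maximum(slope_grid.values, eps))
    out = accum.like(raw)
    if smooth_radius_cells > 0:
        out = mean_filter_circular(out, smooth_radius_cells)
    return out


def _annulus_kernel(inner_cells: float, outer_cells: float) -> np.ndarray:
    r = int(math.ceil(outer_cells))
    ij = np.arange(-r, r + 1)
    di, dj = np.meshgrid(ij, ij, indexing="ij")
    d = np.hypot(di, dj)
    return ((d > inner_cells) & (d <= outer_cells + 1e-12)).astype(float)


def tpi(dem: RasterGrid, inner_radius_m: float = 10.0,
        outer_radius_m: float = 100.0, *, annulus: bool = True) -> RasterGrid:
    """Topographic position index: z(cell) minus mean z of its neighbourhood.

    The neighbourhood is the annulus inner < d <= outer by default; with
    ``annulus=False`` it is the filled disk of the outer radius (centre
    cell excluded).  Windows are clipped at grid edges.
    """
    if outer_radius_m <= inner_radius_m and annulus:
        raise ValueError("outer radius must exceed inner radius")
    cs = dem.cell_size
    if annulus:
        kernel = _annulus_kernel(inner_radius_m / cs, outer_radius_m / cs)
    else:
        kernel = _annulus_kernel(0.0, outer_radius_m / cs)
    mean_z = _focal_mean(dem.values, kernel, use_fft=kernel.size > 1500)
    return dem.like(dem.values - mean_z)


def classify_landforms(tpi_grid: RasterGrid, slope_grid: RasterGrid, *,
                       sd_ridge: float = 1.0, sd_drainage: float = 0.5,
                       slope_threshold_deg: float = 5.0) -> LandformRaster:
    """Five landform classes from standardised TPI plus slope.

    TPI is z-scored over non-nodata cells; z >= +1 SD -> ridge,
    z <= -1 SD -> valley, -1 < z <= -0.5 -> drainage, and the remaining
    mid-range cells are plains where slope stays under the threshold and
    slopes otherwise.  Zero TPI variance degrades to the slope-only rule.
    """
    t = tpi_grid.values
    valid = np.isfinite(t) & np.isfinite(slope_grid.values)
    sd = float(np.std(t[valid])) if np.any(valid) else 0.0
    if sd == 0.0:
        warnings.warn("TPI has zero variance; classifying by slope only")
        zscore = np.zeros_like(t)
    else:
        zscore = (t - float(np.mean(t[valid]))) / sd
    tan_thresh = math.tan(math.radians(slope_threshold_deg))
    flat_or_steep = np.where(slope_grid.values < tan_thresh, PLAIN, SLOPE)
    codes = np.select(
        [zscore >= sd_ridge, zscore <= -sd_ridge, zscore <= -sd_drainage],
        [RIDGE, VALLEY, DRAINAGE],
        default=0,
    ).astype(float)
    codes = np.where(codes == 0, flat_or_steep, codes)
    codes[~valid] = np.nan
    return LandformRaster(tpi_grid.like(codes))


def terrain_stack(dem: RasterGrid, *, mfd_exponent: float = 1.1,
                  twi_smooth_radius: int = 4, tpi_presmooth_radius: int = 5,
                  tpi_inner_m: float = 10.0, tpi_outer_m: float = 100.0,
                  slope_threshold_deg: float = 5.0,
                  twi_eps: float = 0.001, pre_fill_pits: bool = False) -> dict:
    """Run the full terrain chain and return all layers.

    Returns a dict with keys ``slope``, ``accumulation``, ``twi``, ``tpi``
    and ``landform``; TPI is computed on a five-cell-radius mean-filtered
    DEM and TWI is smoothed with a four-cell radius, mirroring the default
    processing chain.
    """
    sl = slope(dem)
    routing_dem = fill_pits(dem) if pre_fill_pits else dem
    acc = mfd_flow_accumulation(routing_dem, exponent=mfd_exponent)
    wet = twi(acc, sl, eps=twi_eps, smooth_radius_cells=twi_smooth_radius)
    dem_smooth = mean_filter_circular(dem, tpi_presmooth_radius)
    position = tpi(dem_smooth, tpi_inner_m, tpi_outer_m)
    landform = classify_landforms(position, sl,
                                  slope_threshold_deg=slope_threshold_deg)
    return {"slope": sl, "accumulation": acc, "twi": wet, "tpi": position,
            "landform": landform}
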