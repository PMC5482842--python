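"""Spatially explicit predictor rasters and their extraction at plants.

Builds the six model predictors on a common 1 m lattice: distance to the
closest large invader canopy, that canopy's area and relative elevation,
vegetation cover, TWI and landform class, then samples them at plant
locations into a fit-ready table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import mapping, shape

from .raster import RasterGrid, check_aligned
from .terrain import LandformRaster, mean_filter_circular

logger = logging.getLogger(__name__)

MIN_CANOPY_AREA_M2 = 6.0

#: model-table predictor columns, in canonical order
PREDICTOR_COLUMNS = ["dist_ac", "log_area_ac", "elev_ac", "log_cover",
                     "twi", "landform"]


@dataclass
class Canopy:
    id: int
    polygon: shapely.Geometry
    area_m2: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.area_m2 is None:
            self.area_m2 = float(self.polygon.area)


@dataclass
class CanopySet:
    """Invader canopy polygons with ids and areas."""

    canopies: list[Canopy] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.canopies)

    def __iter__(self):
        return iter(self.canopies)

    def __getitem__(self, i) -> Canopy:
        return self.canopies[i]

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area_m2 for c in self.canopies])

    def footprint_mask(self, template: RasterGrid, canopy: Canopy) -> np.ndarray:
        """Cells whose centre lies inside the canopy polygon.

        Degenerate footprints (no covered centre) fall back to the cell
        containing the polygon's representative point, so every canopy
        occupies at least one cell.
        """
        poly = canopy.polygon
        minx, miny, maxx, maxy = poly.bounds
        cs = template.cell_size
        x0, y0 = template.origin
        c0 = max(int((minx - x0) / cs) - 1, 0)
        c1 = min(int((maxx - x0) / cs) + 2, template.ncols)
        r0 = max(int((y0 - maxy) / cs) - 1, 0)
        r1 = min(int((y0 - miny) / cs) + 2, template.nrows)
        mask = np.zeros(template.shape, dtype=bool)
        if c1 > c0 and r1 > r0:
            xs = x0 + (np.arange(c0, c1) + 0.5) * cs
            ys = y0 - (np.arange(r0, r1) + 0.5) * cs
            X, Y = np.meshgrid(xs, ys)
            mask[r0:r1, c0:c1] = shapely.contains_xy(poly, X, Y)
        if not mask.any():
            pt = poly.representative_point()
            row, col = template.index_of(pt.x, pt.y)
            mask[row, col] = True
        return mask

    # -- GeoJSON I/O -------------------------------------------------------
    def to_geojson(self, path) -> None:
        features = [
            {"type": "Feature",
             "geometry": mapping(c.polygon),
             "properties": {"id": c.id, "area_m2": c.area_m2}}
            for c in self.canopies
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "CanopySet":
        with open(path) as fh:
            doc = json.load(fh)
        canopies = [
            Canopy(id=int(f["properties"]["id"]), polygon=shape(f["geometry"]),
                   area_m2=float(f["properties"].get("area_m2")
                                 if f["properties"].get("area_m2") is not None
                                 else shape(f["geometry"]).area))
            for f in doc["features"]
        ]
        return cls(canopies)


@dataclass
class PredictorStack:
    """The six co-registered predictor layers."""

    dist_ac: RasterGrid
    area_ac: RasterGrid
    elev_ac: RasterGrid
    twi: RasterGrid
    cover: RasterGrid
    landform: LandformRaster

    def __post_init__(self) -> None:
        check_aligned(self.dist_ac, self.area_ac, self.elev_ac, self.twi,
                      self.cover, self.landform.grid)

    @property
    def template(self) -> RasterGrid:
        return self.dist_ac


def write_stack(stack: PredictorStack, outdir) -> list:
    """Write the six layers as ASCII grids plus a landform legend sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in ("dist_ac", "area_ac", "elev_ac", "twi", "cover"):
        p = outdir / f"{name}.asc"
        getattr(stack, name).write_ascii(p)
        paths.append(p)
    p = outdir / "landform.asc"
    stack.landform.grid.write_ascii(p)
    paths.append(p)
    p = outdir / "landform_legend.json"
    with open(p, "w") as fh:
        json.dump({str(k): v for k, v in stack.landform.legend.items()}, fh)
    paths.append(p)
    return paths


def read_stack(indir) -> PredictorStack:
    """Read a predictor stack written by :func:`write_stack`."""
    from pathlib import Path

    indir = Path(indir)
    layers = {name: RasterGrid.read_ascii(indir / f"{name}.asc")
              for name in ("dist_ac", "area_ac", "elev_ac", "twi", "cover")}
    lf = RasterGrid.read_ascii(indir / "landform.asc")
    with open(indir / "landform_legend.json") as fh:
        legend = {int(k): v for k, v in json.load(fh).items()}
    return PredictorStack(landform=LandformRaster(lf, legend), **layers)


def filter_canopies(canopies: CanopySet,
                    min_area_m2: float = MIN_CANOPY_AREA_M2) -> CanopySet:
    """Keep canopies strictly larger than ``min_area_m2``."""
    kept = [c for c in canopies if c.area_m2 > min_area_m2]
    if not kept:
        raise ValueError(f"no qualifying canopies (area > {min_area_m2} m^2)")
    return CanopySet(kept)


def _per_canopy_distances(canopies: CanopySet, template: RasterGrid):
    """Per-canopy Euclidean cell-centre distance fields (m)."""
    cs = template.cell_size
    fields = []
    for canopy in canopies:
        mask = canopies.footprint_mask(template, canopy)
        d = ndimage.distance_transform_edt(~mask, sampling=cs)
        fields.append(d)
    return fields


def distance_to_canopy(canopies: CanopySet, template: RasterGrid) -> RasterGrid:
    """Distance (m) from each cell centre to the nearest canopy footprint cell."""
    if len(canopies) == 0:
        raise ValueError("empty canopy set")
    dists = _per_canopy_distances(canopies, template)
    return template.like(np.min(np.stack(dists), axis=0))


def nearest_canopy_attributes(canopies: CanopySet, template: RasterGrid,
                              dem: RasterGrid, *, reference: str = "mean"):
    """(area_ac, elev_ac) rasters for the nearest canopy of every cell.

    The nearest canopy is decided by footprint-cell-centre distance with
    ties awarded to the lowest canopy id.  ``elev_ac`` is the cell's DEM
    elevation minus the canopy's reference elevation (mean DEM over its
    footprint by default; 'centroid' and 'min' are alternatives), so
    negative values mean the cell lies below the canopy.
    """
    check_aligned(template, dem)
    dists = np.stack(_per_canopy_distances(canopies, template))
    winner = np.argmin(dists, axis=0)  # argmin -> first (lowest id) on ties
    ref_z = []
    for canopy in canopies:
        mask = canopies.footprint_mask(template, canopy)
        zs = dem.values[mask]
        if reference == "mean":
            ref_z.append(float(np.nanmean(zs)))
        elif reference == "min":
            ref_z.append(float(np.nanmin(zs)))
        elif reference == "centroid":
            pt = canopy.polygon.representative_point()
            row, col = template.index_of(pt.x, pt.y)
            ref_z.append(float(dem.values[row, col]))
        else:
            raise ValueError(f"unknown canopy reference elevation rule {reference!r}")
    areas = canopies.areas
    area_ac = template.like(areas[winner])
    elev_ac = template.like(dem.values - np.asarray(ref_z)[winner])
    return area_ac, elev_ac


def cover_from_classified_points(points: pd.DataFrame, template: RasterGrid, *,
                                 smooth_radius_cells: int = 6,
                                 bounded: bool = True) -> RasterGrid:
    """Percent vegetation cover from ground / non-ground classified returns.

    ``points`` needs columns x, y, cls with cls in {'ground', 'nonground'}.
    Per cell the bounded form is 100 * nonground / (ground + nonground);
    with ``bounded=False`` the raw nonground/ground ratio (x100, capped at
    nothing) is used instead.  Cells with no points are nodata.  The raw
    field is then mean-filtered (six-cell radius by default).
    """
    row, col = template.index_of(points["x"].to_numpy(), points["y"].to_numpy())
    is_veg = points["cls"].to_numpy() == "nonground"
    n_veg = np.zeros(template.shape)
    n_all = np.zeros(template.shape)
    np.add.at(n_veg, (row, col), is_veg.astype(float))
    np.add.at(n_all, (row, col), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if bounded:
            cover = np.where(n_all > 0, 100.0 * n_veg / np.maximum(n_all, 1), np.nan)
        else:
            n_ground = n_all - n_veg
            cover = np.where(n_all > 0,
                             100.0 * n_veg / np.maximum(n_ground, 1e-12), np.nan)
    out = template.like(cover)
    if smooth_radius_cells > 0:
        out = mean_filter_circular(out, smooth_radius_cells)
    return out


def build_stack(dem: RasterGrid, cover: RasterGrid, canopies: CanopySet,
                twi: RasterGrid, landform: LandformRaster, *,
                min_canopy_area_m2: float = MIN_CANOPY_AREA_M2,
                elev_reference: str = "mean") -> PredictorStack:
    """Assemble the six predictor layers on the DEM's lattice."""
    big = filter_canopies(canopies, min_canopy_area_m2)
    dist = distance_to_canopy(big, dem)
    area_ac, elev_ac = nearest_canopy_attributes(big, dem, dem,
                                                 reference=elev_reference)
    return PredictorStack(dist_ac=dist, area_ac=area_ac, elev_ac=elev_ac,
                          twi=twi, cover=cover, landform=landform)


def extract_at_points(stack: PredictorStack, plants: pd.DataFrame) -> pd.DataFrame:
    """Sample every predictor at plant locations (nearest cell).

    Applies the log transforms used in the model: log(area) and
    log(cover + 1).  Rows with any nodata predictor are dropped with a
    warning; plants outside the raster extent raise.
    """
    x = plants["x"].to_numpy(dtype=float)
    y = plants["y"].to_numpy(dtype=float)
    row, col = stack.template.index_of(x, y)  # raises if outside extent

    table = plants.reset_index(drop=True).copy()
    table["dist_ac"] = stack.dist_ac.values[row, col]
    table["log_area_ac"] = np.log(stack.area_ac.values[row, col])
    table["elev_ac"] = stack.elev_ac.values[row, col]
    table["log_cover"] = np.log(stack.cover.values[row, col] + 1.0)
    table["twi"] = stack.twi.values[row, col]
    codes = stack.landform.grid.values[row, col]
    names = np.full(codes.shape, "", dtype=object)
    for code, name in stack.landform.legend.items():
        names[codes == code] = name
    table["landform"] = names

    numeric = ["dist_ac", "log_area_ac", "elev_ac", "log_cover", "twi"]
    bad = table[numeric].isna().any(axis=1) | (table["landform"] == "")
    if bad.any():
        logger.warning("dropping %d plant row(s) with nodata predictors",
                       int(bad.sum()))
        table = table.loc[~bad].reset_index(drop=True)
    return table
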