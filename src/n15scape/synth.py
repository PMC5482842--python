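"""Synthetic dune-landscape scenarios with known d15N structure.

Generates a DEM with ridge-and-swale topography, invader canopy polygons,
a patchy vegetation-cover raster, a plot/transect sampling design and
plant-level d15N values composed from known ("truth") component effects
plus nested random intercepts and residual noise.  Every stage is a pure
function of its configuration and the top-level seed, so downstream
estimation can be tested by parameter recovery.

Component effect shapes are smooth monotone forms whose spans are
calibrated to the realised covariate distribution: about +3 permil
enrichment at the canopy edge decaying to zero by 8 m, about +2 permil for
plants below the canopy, 0 to +1 permil with the log canopy area, about
5 permil across the log cover range, a linear decrease of about 4 permil
across the TWI range, and landform offsets with valleys/drainages highest
and plains lowest.  Each component is mean-centred over the realised
sample so the configured intercept carries the overall level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely import affinity
from shapely.geometry import LineString, Point

from .predictors import Canopy, CanopySet, PredictorStack, build_stack, \
    extract_at_points, filter_canopies
from .raster import RasterGrid
from .terrain import terrain_stack

logger = logging.getLogger(__name__)

RASTER_BUFFER_M = 100.0  # rasters cover this buffer around sampled plants


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    extent_m: tuple = (420.0, 420.0)
    cell_size_m: float = 1.0
    n_plots: int = 8
    transects_per_plot: int = 4
    transect_length_m: float = 20.0
    # per-transect plant counts; mean 14 keeps the expected total near the
    # 450-plant design (8 plots x 4 transects)
    plants_per_transect_mean: float = 14.0
    plants_per_transect_sd: float = 3.0
    n_canopies: int = 12
    canopy_area_range_m2: tuple = (8.3, 564.7)
    noise_sd_permil: float = 1.8
    intercept_permil: float = -5.84
    plot_re_sd_permil: float = 0.9
    transect_re_sd_permil: float = 0.6
    seed: int = 0
    # DEM components: anisotropic sinusoidal ridges + correlated noise + tilt
    dem_amplitudes_m: tuple = (3.0, 1.1)
    dem_wavelengths_m: tuple = (95.0, 41.0)
    dem_azimuths_deg: tuple = (25.0, 80.0)
    dem_noise_sd_m: float = 0.5
    dem_noise_corr_m: float = 12.0
    dem_tilt: float = 0.004
    cover_corr_m: float = 8.0

    def __post_init__(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0 or self.cell_size_m <= 0:
            raise ConfigurationError("extent and cell size must be positive")
        if self.canopy_area_range_m2[0] <= 6.0:
            raise ConfigurationError("canopy area range must start above 6 m^2")
        for sd in (self.plants_per_transect_sd, self.noise_sd_permil,
                   self.plot_re_sd_permil, self.transect_re_sd_permil):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        if self.n_canopies < max(self.n_plots, 1):
            raise ConfigurationError("need at least as many canopies as plots")
        # extent must hold the plots plus the 100 m raster buffer
        a_max = math.sqrt(self.canopy_area_range_m2[1] * 2.0 / math.pi)
        margin = RASTER_BUFFER_M + self.transect_length_m + a_max
        if min(self.extent_m) <= 2 * margin + 10:
            raise ConfigurationError(
                f"extent {self.extent_m} too small for {self.n_plots} plots "
                f"with a {RASTER_BUFFER_M:.0f} m margin")

    def grid_template(self) -> RasterGrid:
        w, h = self.extent_m
        cs = self.cell_size_m
        shape = (int(round(h / cs)), int(round(w / cs)))
        return RasterGrid(np.zeros(shape), cs, origin=(0.0, h))

    def stage_rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage child generator of the top-level seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


def generate_dem(config: SimulationConfig) -> RasterGrid:
    """Smooth DEM: superposed anisotropic sine ridges, low-frequency
    correlated noise and a gentle regional tilt.  No nodata cells."""
    rng = config.stage_rng(1)
    template = config.grid_template()
    X, Y = template.cell_centers()
    z = np.zeros(template.shape)
    for amp, lam, az in zip(config.dem_amplitudes_m, config.dem_wavelengths_m,
                            config.dem_azimuths_deg):
        theta = math.radians(az)
        u = X * math.cos(theta) + Y * math.sin(theta)
        z += amp * np.sin(2 * np.pi * u / lam + rng.uniform(0, 2 * np.pi))
    if config.dem_noise_sd_m > 0:
        noise = rng.standard_normal(template.shape)
        noise = ndimage.gaussian_filter(
            noise, sigma=config.dem_noise_corr_m / config.cell_size_m)
        sd = noise.std()
        if sd > 0:
            z += noise * (config.dem_noise_sd_m / sd)
    if config.dem_tilt:
        tilt_az = rng.uniform(0, 2 * np.pi)
        z += config.dem_tilt * (X * math.cos(tilt_az) + Y * math.sin(tilt_az))
    return template.like(z + 30.0)


def _ellipse(center, area, aspect, angle_deg) -> shapely.Geometry:
    a = math.sqrt(area * aspect / math.pi)
    b = area / (math.pi * a)
    poly = Point(0.0, 0.0).buffer(1.0, quad_segs=48)
    poly = affinity.scale(poly, a, b)
    poly = affinity.rotate(poly, angle_deg)
    poly = affinity.translate(poly, *center)
    # polygonal approximation slightly under-covers the ellipse; rescale
    poly = affinity.scale(poly, *(math.sqrt(area / poly.area),) * 2,
                          origin="centroid")
    return poly


def generate_canopies(config: SimulationConfig, dem: RasterGrid) -> CanopySet:
    """Random elliptical canopies with log-uniform areas.

    The first two canopies take the extremes of the configured area range
    (so the realised areas span it, as in the observed data); the rest are
    log-uniform draws.  The first ``n_plots`` canopies are placed on a
    jittered grid that leaves room for transects plus the raster buffer;
    extra canopies are scattered with a minimum separation.
    """
    if config.n_canopies < 1:
        raise ConfigurationError("n_canopies must be >= 1")
    rng = config.stage_rng(2)
    lo, hi = config.canopy_area_range_m2
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_canopies))
    if config.n_canopies >= 2 and hi > lo:
        areas[0], areas[1] = hi, lo

    a_max = math.sqrt(hi * 2.0 / math.pi)
    margin = RASTER_BUFFER_M + config.transect_length_m + a_max
    w, h = config.extent_m
    x0, x1 = margin, w - margin
    y0, y1 = margin, h - margin
    if x1 <= x0 or y1 <= y0:
        raise GenerationError("extent too small to place canopies")

    min_plot_spacing = 2 * a_max + 8.0
    nx = max(int((x1 - x0) // min_plot_spacing) + 1, 1)
    ny = max(int((y1 - y0) // min_plot_spacing) + 1, 1)
    if nx * ny < config.n_plots:
        raise GenerationError("extent too small to place canopies without "
                              "full overlap")
    gx = np.linspace(x0, x1, nx)
    gy = np.linspace(y0, y1, ny)
    sites = [(xx, yy) for xx in gx for yy in gy]
    order = rng.permutation(len(sites))
    jit = min(min_plot_spacing / 4.0,
              (gx[1] - gx[0]) / 3.0 if nx > 1 else 5.0)

    centers: list[tuple] = []
    for i in range(config.n_canopies):
        if i < config.n_plots:
            sx, sy = sites[order[i]]
            centers.append((sx + rng.uniform(-jit, jit),
                            sy + rng.uniform(-jit, jit)))
        else:
            for _ in range(200):
                cand = (rng.uniform(x0, x1), rng.uniform(y0, y1))
                if all(math.hypot(cand[0] - cx, cand[1] - cy) >= 15.0
                       for cx, cy in centers):
                    centers.append(cand)
                    break
            else:
                raise GenerationError("could not place extra canopy "
                                      "without full overlap")

    canopies = []
    for i, (center, area) in enumerate(zip(centers, areas)):
        poly = _ellipse(center, float(area), rng.uniform(1.0, 1.8),
                        rng.uniform(0.0, 180.0))
        canopies.append(Canopy(id=i, polygon=poly))
    return CanopySet(canopies)


def generate_cover(config: SimulationConfig, canopies: CanopySet,
                   template: RasterGrid | None = None) -> RasterGrid:
    """Patchy percent-cover raster in [0, 100].

    A correlated Gaussian field is rank-transformed and mapped so that
    roughly a tenth of the cells are bare sand (0%) and the upper tail
    reaches 95%; invader footprints are forced to 100%.
    """
    rng = config.stage_rng(3)
    template = template or config.grid_template()
    noise = rng.standard_normal(template.shape)
    fieldv = ndimage.gaussian_filter(noise,
                                     sigma=config.cover_corr_m / template.cell_size)
    ranks = fieldv.argsort(axis=None).argsort(axis=None).reshape(fieldv.shape)
    r = ranks / (ranks.size - 1.0)
    cover = np.clip(140.0 * r - 25.0, 0.0, 95.0)
    for canopy in canopies:
        cover[canopies.footprint_mask(template, canopy)] = 100.0
    return template.like(cover)


def _edge_point(polygon, center, direction) -> np.ndarray:
    """Point where a ray from the canopy centre exits the polygon."""
    far = center + direction * 500.0
    hit = polygon.exterior.intersection(LineString([tuple(center), tuple(far)]))
    if hit.is_empty:
        return np.asarray(center, dtype=float)
    pts = ([hit] if isinstance(hit, Point) else list(getattr(hit, "geoms", [])))
    pts = [p for p in pts if isinstance(p, Point)]
    if not pts:
        return np.asarray(center, dtype=float)
    best = max(pts, key=lambda p: (p.x - center[0]) ** 2 + (p.y - center[1]) ** 2)
    return np.array([best.x, best.y])


#: cardinal transect directions: N, E, S, W (azimuth 0/90/180/270 degrees)
_DIRECTIONS = [(0.0, 1.0), (1.0, 0.0), (0.0, -1.0), (-1.0, 0.0)]


def layout_sampling(config: SimulationConfig, canopies: CanopySet,
                    template: RasterGrid | None = None) -> pd.DataFrame:
    """Plot/transect/plant sampling design around the plot canopies.

    Each of the first ``n_plots`` qualifying canopies (area > 6 m^2) hosts
    a plot with transects running N/E/S/W from the canopy edge; plants are
    placed at jittered spacing along each transect with a little lateral
    scatter.  Transects reaching outside the raster are truncated with a
    warning.  Returns a table of plant locations only.
    """
    rng = config.stage_rng(4)
    template = template or config.grid_template()
    big = filter_canopies(canopies)
    if len(big) < config.n_plots:
        raise GenerationError(f"need >= {config.n_plots} canopies larger "
                              f"than 6 m^2, have {len(big)}")
    xmin, ymin, xmax, ymax = template.extent
    pad = template.cell_size  # keep plants strictly inside the raster
    rows = []
    plant_no = 0
    for p in range(config.n_plots):
        canopy = big[p]
        center = np.array([canopy.polygon.centroid.x, canopy.polygon.centroid.y])
        for d in range(config.transects_per_plot):
            direction = np.asarray(_DIRECTIONS[d % 4])
            perp = np.array([-direction[1], direction[0]])
            start = _edge_point(canopy.polygon, center, direction)
            n_plants = max(1, int(round(rng.normal(
                config.plants_per_transect_mean, config.plants_per_transect_sd))))
            truncated = 0
            for j in range(n_plants):
                t = ((j + rng.uniform(0.25, 0.75)) / n_plants
                     * config.transect_length_m)
                pt = start + direction * t + perp * rng.uniform(-0.5, 0.5)
                if not (xmin + pad <= pt[0] <= xmax - pad
                        and ymin + pad <= pt[1] <= ymax - pad):
                    truncated += 1
                    continue
                plant_no += 1
                rows.append({"plant_id": f"pl{plant_no:04d}",
                             "plot_id": f"P{p + 1}",
                             "transect_id": f"T{d + 1}",
                             "x": pt[0], "y": pt[1]})
            if truncated:
                logger.warning("plot P%d transect T%d truncated: %d plant(s) "
                               "outside the raster", p + 1, d + 1, truncated)
    return pd.DataFrame(rows)


@dataclass
class TruthModel:
    """Known component effects (centred over the realised sample)."""

    f_dist: callable
    f_elev: callable
    f_logarea: callable
    f_logcover: callable
    f_twi: callable
    landform_offsets: dict
    centers: dict = field(default_factory=dict)

    _SMOOTH = {"dist_ac": "f_dist", "elev_ac": "f_elev",
               "log_area_ac": "f_logarea", "log_cover": "f_logcover",
               "twi": "f_twi"}

    def component(self, term: str, values) -> np.ndarray:
        """Centred truth component for one predictor."""
        if term == "landform":
            off = self.landform_offsets
            c = self.centers.get("landform", 0.0)
            return np.array([off[v] for v in values]) - c
        fn = getattr(self, self._SMOOTH[term])
        return fn(np.asarray(values, dtype=float)) - self.centers.get(term, 0.0)

    def components(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = {t: self.component(t, table[t].to_numpy())
                for t in self._SMOOTH}
        cols["landform"] = self.component("landform",
                                          table["landform"].to_numpy())
        return pd.DataFrame(cols)

    def linear_predictor(self, table: pd.DataFrame, intercept: float) -> np.ndarray:
        return intercept + self.components(table).sum(axis=1).to_numpy()


def _raw_dist(d, span=3.0, scale=3.2, cutoff=8.0):
    d = np.asarray(d, dtype=float)
    tail = math.exp(-((cutoff / scale) ** 2))
    val = span * (np.exp(-((d / scale) ** 2)) - tail) / (1.0 - tail)
    return np.where(d >= cutoff, 0.0, np.maximum(val, 0.0))


def calibrate_truth(table: pd.DataFrame, *, dist_span: float = 3.0,
                    elev_span: float = 3.4, area_span: float = 1.0,
                    cover_span: float = 5.0, twi_span: float = 4.0) -> TruthModel:
    """Build the truth model calibrated to the realised covariates.

    Cover, TWI and canopy-area components are scaled to their target spans
    over the observed covariate range; all components are then centred to
    mean zero over the sample.  ``area_span=0`` (or any other zero span)
    switches that component off entirely.
    """
    la = table["log_area_ac"].to_numpy(dtype=float)
    lc = table["log_cover"].to_numpy(dtype=float)
    tw = table["twi"].to_numpy(dtype=float)
    la_lo, la_rng = float(la.min()), max(float(np.ptp(la)), 1e-9)
    lc_lo, lc_rng = float(lc.min()), max(float(np.ptp(lc)), 1e-9)
    tw_lo, tw_rng = float(tw.min()), max(float(np.ptp(tw)), 1e-9)

    def f_dist(d):
        return _raw_dist(d, span=dist_span)

    def f_elev(e):
        return elev_span / (1.0 + np.exp(np.asarray(e, dtype=float) / 0.8))

    # sigmoid rising late in the log-area range: flat for small canopies,
    # ~ +area_span for the largest
    c = la_lo + 0.75 * la_rng
    s = la_rng / 8.0

    def _area_raw(v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - c) / s))

    gain = area_span / max(float(_area_raw(la_lo + la_rng) - _area_raw(la_lo)),
                           1e-9) if area_span else 0.0

    def f_logarea(v):
        return gain * (_area_raw(v) - _area_raw(la_lo))

    def f_logcover(v):
        return cover_span * (np.asarray(v, dtype=float) - lc_lo) / lc_rng

    def f_twi(v):
        return -twi_span * (np.asarray(v, dtype=float) - tw_lo) / tw_rng

    offsets = {"valley": 1.5, "drainage": 1.2, "ridge": 0.1, "slope": 0.0,
               "plain": -1.2}
    truth = TruthModel(f_dist=f_dist, f_elev=f_elev, f_logarea=f_logarea,
                       f_logcover=f_logcover, f_twi=f_twi,
                       landform_offsets=offsets)
    truth.centers = {
        "dist_ac": float(np.mean(f_dist(table["dist_ac"].to_numpy()))),
        "elev_ac": float(np.mean(f_elev(table["elev_ac"].to_numpy()))),
        "log_area_ac": float(np.mean(f_logarea(la))),
        "log_cover": float(np.mean(f_logcover(lc))),
        "twi": float(np.mean(f_twi(tw))),
        "landform": float(np.mean([offsets[v] for v in table["landform"]])),
    }
    return truth


def generate_delta15n(table: pd.DataFrame, truth: TruthModel,
                      config: SimulationConfig) -> pd.DataFrame:
    """Compose observed d15N from truth components, nested random
    intercepts and residual noise; realised effects are kept for recovery
    tests."""
    needed = ["dist_ac", "log_area_ac", "elev_ac", "log_cover", "twi"]
    missing = table[needed].isna().any(axis=1) | (table["landform"] == "")
    if missing.any():
        ids = table.loc[missing, "plant_id"].tolist()
        raise ValueError(f"missing predictor values for plants {ids[:5]}"
                         + ("..." if len(ids) > 5 else ""))
    rng = config.stage_rng(5)
    out = table.copy()
    out["d15n_true"] = truth.linear_predictor(out, config.intercept_permil)

    plot_levels = sorted(out["plot_id"].unique())
    b_plot = dict(zip(plot_levels,
                      rng.normal(0.0, config.plot_re_sd_permil,
                                 len(plot_levels))))
    tkeys = sorted((out["plot_id"] + "/" + out["transect_id"]).unique())
    b_tr = dict(zip(tkeys, rng.normal(0.0, config.transect_re_sd_permil,
                                      len(tkeys))))
    out["re_plot"] = out["plot_id"].map(b_plot)
    out["re_transect"] = (out["plot_id"] + "/" + out["transect_id"]).map(b_tr)
    eps = rng.normal(0.0, config.noise_sd_permil, len(out))
    out["d15n_obs"] = out["d15n_true"] + out["re_plot"] + out["re_transect"] + eps
    return out


@dataclass
class ScenarioBundle:
    dem: RasterGrid
    cover: RasterGrid
    canopies: CanopySet
    stack: PredictorStack
    table: pd.DataFrame
    truth: TruthModel
    config: SimulationConfig
    terrain: dict = field(default_factory=dict)


def build_scenario(config: SimulationConfig | None = None,
                   truth_kwargs: dict | None = None) -> ScenarioBundle:
    """Run the full generation chain: DEM -> canopies -> cover -> terrain
    -> predictor stack -> sampling design -> extraction -> d15N."""
    config = config or SimulationConfig()
    dem = generate_dem(config)
    canopies = generate_canopies(config, dem)
    cover = generate_cover(config, canopies, dem)
    layers = terrain_stack(dem)
    stack = build_stack(dem, cover, canopies, layers["twi"], layers["landform"])
    plants = layout_sampling(config, canopies, dem)
    table = extract_at_points(stack, plants)
    truth = calibrate_truth(table, **(truth_kwargs or {}))
    table = generate_delta15n(table, truth, config)
    return ScenarioBundle(dem=dem, cover=cover, canopies=canopies, stack=stack,
                          table=table, truth=truth, config=config,
                          terrain=layers)


def write_scenario(bundle: ScenarioBundle, outdir) -> list:
    """Write all scenario artefacts as text files; returns written paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path):
        written.append(path)
        return path

    bundle.dem.write_ascii(_w(outdir / "dem.asc"))
    bundle.cover.write_ascii(_w(outdir / "cover.asc"))
    bundle.canopies.to_geojson(_w(outdir / "canopies.geojson"))
    cols = ["plant_id", "plot_id", "transect_id", "x", "y",
            "d15n_true", "d15n_obs"]
    bundle.table[cols].to_csv(_w(outdir / "plants.csv"), index=False)
    bundle.table.to_csv(_w(outdir / "table.csv"), index=False)
    for name in ("twi", "tpi", "slope", "accumulation"):
        bundle.terrain[name].write_ascii(_w(outdir / f"{name}.asc"))
    bundle.terrain["landform"].grid.write_ascii(_w(outdir / "landform.asc"))
    import json as _json
    with open(_w(outdir / "landform_legend.json"), "w") as fh:
        _json.dump(bundle.terrain["landform"].legend, fh)
    return written
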