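# n15scape

Community-scale foliar δ¹⁵N isoscape modelling, end to end on synthetic
dune landscapes:

1. **synthetic landscapes** (`n15scape.synth`) — DEM with ridge-and-swale
   topography, invader canopy polygons, patchy vegetation cover, a
   plot/transect sampling design and plant-level δ¹⁵N composed from known
   component effects plus nested random intercepts and residual noise;
2. **terrain derivatives** (`n15scape.terrain`) — circular mean filters,
   slope, multiple-flow-direction accumulation, TWI = ln(a/tanβ), annular
   TPI and a five-class landform map (ridge/slope/plain/drainage/valley);
3. **predictors** (`n15scape.predictors`) — distance to the closest large
   canopy, that canopy's area and relative elevation, cover, TWI and
   landform, rasterised on one 1 m lattice and extracted at plant points;
4. **additive mixed model** (`n15scape.gamm`) — thin-plate regression
   spline smooths + landform factor + nested plot/transect random
   intercepts, fitted by exact maximum likelihood in mixed-model form;
   predictions, centred partial effects with 95% CIs, effective degrees of
   freedom;
5. **model selection** (`n15scape.selection`) — all-subsets AICc ranking
   with Akaike weights;
6. **validation** (`n15scape.validation`) — repeated 75/25 random-split
   R²/RMSE plus Moran's I correlograms and experimental semivariograms for
   residual diagnostics;
7. **isoscapes** (`n15scape.isoscape`) — continuous fixed-effect δ¹⁵N
   rasters, masked beyond the training canopy-distance range, and
   scenario decomposition maps (single predictors varying, others held at
   training constants).

Rasters are plain-text ESRI ASCII grids; vector data are GeoJSON; tables
are CSV. Everything is deterministic given a seed.

## CLI

```sh
n15scape run --config run.yaml --out outdir/ --seed 1   # full pipeline
n15scape simulate --out scenario/ --seed 1
n15scape terrain --dem dem.asc --out layers/
n15scape predictors --dem dem.asc --cover cover.asc \
    --canopies canopies.geojson --plants plants.csv --out pred/
n15scape fit --table table.csv --out fit.json
n15scape select --table table.csv --out selection.csv
n15scape validate --table table.csv --runs 100 --seed 1 --out val.json
n15scape isoscape --fit fit.json --stack pred/ --table table.csv \
    --out map.asc [--vary dist_ac,log_cover]
```

`run` writes a manifest (config hash, per-file checksums, stage timings)
and skips stages whose outputs are already up to date unless `--force`.

The YAML config accepts any `SimulationConfig` field, e.g.

```yaml
extent_m: [420, 420]
n_plots: 8
canopy_area_range_m2: [8.3, 564.7]
noise_sd_permil: 1.8
seed: 1
```

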