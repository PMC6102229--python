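# ridge2reef

A linked land-sea modeling pipeline for ridge-to-reef conservation
planning.  It chains:

1. **Watershed sediment export** — per-cell annual soil loss
   (R·K·LS·C·P with the practice factor fixed at 1, Desmet–Govers LS,
   Bols rainfall erosivity), D8 flow routing over a depression-filled DEM,
   a hydrologic connectivity index `IC = log10(D_up / D_dn)`, and the
   logistic delivery-ratio curve `SDR = SDR_max / (1 + exp((IC0 − IC)/k))`
   (defaults `IC0 = 0.5`, `k = 2.0`, `SDR_max = 0.8`), with per-watershed
   loads summed to shoreline pour points.
2. **Coastal plume dispersal** — least-accumulated-cost surfaces from each
   pour point (weighted blend of normalized depth, distance to stream
   mouth, and wind exposure) and the decay `S = s_p · exp(−c²/D_c)`,
   clipped at 3 km from the shoreline; plumes are summed into a TSS proxy
   grid.
3. **Marine drivers** — depth, distance from shore, bathymetric position
   index (60 m and 240 m radii), slope, slope of slope, planar/profile
   curvature, aspect with circular statistics (northness/eastness,
   circular SD), and habitat-connectivity metrics (contiguity, fractal
   dimension, proximity, Shannon diversity).
4. **Reef indicator models** — Gaussian boosted regression trees per
   indicator (four benthic groups on a square-root scale, four fish groups
   on a fourth-root scale with benthic covers as extra predictors), tuned
   by ten-fold CV over learning rate / tree complexity / bag fraction with
   stagewise tree-count selection, after greedy removal of predictors
   correlated above |r| = 0.7; diagnostics include PDE, CV PDE, relative
   influence, partial-dependence response curves, and Moran's I on
   residuals.  Prediction maps cover reef cells to 22 m depth at 60 m
   resolution.
5. **Scenario construction** — land-use change rules on capability
   classes (deforestation: classes V–VII inside logging concessions become
   pine plantation, I–IV outside become monoculture; restoration: pine
   back to native forest) and depth-stratified proportional bleaching
   reductions of predicted coral cover.
6. **Impact assessment** — per-cell two-sided significance of prediction
   differences against the domain-wide difference distribution
   (α = 0.10), stressor-overlay categories with additive changes, and
   per-indicator area/biomass summary tables.
7. **Prioritization** — watersheds linked to significant reef areas by the
   >90 % cumulative plume-contribution rule, priority land cells by the
   >66 % cumulative-export rule (or significant export change), buffered
   by 100 m into management polygons.

A first-class **synthetic island** module generates a deterministic test
fixture — a three-valley volcanic island with land-cover mosaic,
capability classes, orographic rainfall, barrier-reef bathymetry, habitat
classes, and reef surveys built from known monotone driver effects — so
the full pipeline runs and validates with no external data.

## CLI

```bash
# full pipeline on the synthetic island
ridge2reef run --scenario deforestation --bleaching high --seed 1 --outdir out/

# synthetic island bundle only
ridge2reef synth --seed 1 --size 200 --outdir island/

# per-stage runs (deterministic re-runs that stop after the stage's outputs)
ridge2reef sediment --seed 1 --outdir out/
ridge2reef plume    --seed 1 --outdir out/
```

`ridge2reef run --no-fast` uses the full published hyperparameter search
grid (lr ∈ {0.01, 0.005, 0.001}, tc ∈ {1, 2, 3, 5}, bag ∈ {0.5, 0.75},
up to 10,000 trees); the default `--fast` grid finishes in minutes with
equivalent qualitative behavior.  All parameters can also be set through
a YAML config (`--config cfg.yml`); every published parameter value is the
default.

## File formats

Rasters are single-band TIFFs with georeferencing (cell size, origin,
nodata, CRS) as JSON in the image-description tag; vectors are GeoJSON;
tables are CSV; configuration is YAML.  Coordinates are projected meters,
row-major from the upper-left corner, cell centers as locations.

## Layout

```
src/ridge2reef/
  core_io/            # Grid/PointTable, raster+vector I/O, config
  synthetic_island.py # deterministic test fixture with known effects
  sediment_export.py  # erosivity, routing, LS, connectivity, SDR, loads
  coastal_plume.py    # cost surfaces, decay dispersal, TSS proxy
  marine_drivers.py   # terrain, exposure, habitat metrics
  reef_models.py      # boosted-tree fitting, diagnostics, prediction
  scenario_builder.py # land-use rules, bleaching reductions
  impact_assessment.py# significance-of-difference, overlays, summaries
  prioritization.py   # watershed linkage, priority areas, buffers
  pipeline.py, cli.py # orchestration and the ridge2reef CLI
```
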