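# defaunation

Hurdle mixed models and gridded projection of hunting-induced mammal
defaunation.

The package implements a reusable pipeline around hunted/unhunted abundance
ratios:

1. **Ratio database** (`defaunation.ratio_db`) — validated record schema,
   response ratio `RR = ln(X_h / X_c)`, and the zero/nonzero split that feeds
   the hurdle model (records with a hunted abundance of zero are local
   extirpations).
2. **Predictor conditioning** (`defaunation.predictors`) — z-standardization,
   a pairwise collinearity screen (flag-only), travel-time interpolation
   between the 2000/2015 endpoint maps, livestock-biomass conversion, and a
   distance-to-nearest-settlement layer on a planar equal-area grid.
3. **Hurdle mixed model** (`defaunation.mixed`, `defaunation.hurdle`) — a
   binomial (logit) mixed model for persistence and a Gaussian mixed model
   for nonzero RRs, both with crossed random intercepts (country / study /
   species). Estimation is authored in-package: profiled ML/REML for the
   Gaussian stage, Laplace-approximate ML (lme4-style) for the binomial
   stage, with adaptive Gauss-Hermite quadrature available for single-factor
   models. BIC selection (ΔBIC ≤ 2 supported set, fewest-parameter tie
   rule), marginal/conditional/semi-partial R².
4. **Cross-validation** (`defaunation.crossval`) — 5-fold CV on the combined
   hurdle prediction, three defaunation categories (low ≤ 0.1 <
   moderate ≤ 0.7 < high), one-vs-rest sensitivity / specificity / balanced
   accuracy, and pseudo-R².
5. **Projection** (`defaunation.projection`) — per-species defaunation index
   `DI_s = 1 − p_persist · min(exp(rr_hat), 1)` over gridded landscapes,
   composite / size-class / trophic-guild maps, hotspot fractions
   (share of species with `DI_s > 0.7`; hotspot at ≥ 1/3).
6. **MESS** (`defaunation.mess`) — multivariate environmental similarity
   surface with the most-dissimilar-variable map.
7. **Overlays** (`defaunation.overlays`) — defaunated/intact area fractions
   (strict `DI > 0.1`), wilderness (`HF ≤ 2`), per-zone mean DI with CIs.
8. **Synthetic data** (`defaunation.simulate`) — databases generated from a
   known hurdle model with crossed random intercepts, plus raster landscapes
   (settlement-distance, smooth HPD/stunting fields, protection/country
   grids, species range masks), so the whole pipeline is testable offline.

Rasters are plain-text ESRI ASCII grids (`.asc`) handled by
`defaunation.raster`; fitted models serialize to JSON.

## CLI

```bash
defaunation simulate --config config.yaml --out outdir/   # synthetic data
defaunation data validate records.csv                     # schema checks
defaunation predictors build --settlements pts.csv --template hpd.asc --out d.asc
defaunation fit --records records.csv --stage gaussian --out fit.json
defaunation select --records records.csv --terms distance_access,body_mass,hpd --out sel/
defaunation evaluate --records records.csv --k 5 --out eval/
defaunation project --records records.csv --rasters outdir/ --out maps/
defaunation mess --records records.csv --rasters outdir/ --out mess/
defaunation overlay --di maps/di_composite.asc --mask outdir/if_mask.asc --out overlay.json
defaunation run --config config.yaml --out run1/          # full chain + manifest
```

`run` expects a YAML config with a `simulate` block (see
`tests/test_cli.py` for a minimal example) and writes a `manifest.json`
with SHA-256 checksums of every stage output; re-running with the same
config and seed reproduces the checksums.

## Record CSV schema

Columns (one row per species × site contrast):
`study_id, country_id, species_id, body_mass (kg), diet_guild
(frugivore|herbivore|insectivore|omnivore|carnivore), abundance_hunted,
abundance_control (> 0), distance_access (km), hpd (ind/km²), stunting
([0,1]), travel_time (min), livestock_biomass (kg/km²), literacy ([0,1]),
protected (bool), year`.
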