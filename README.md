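# nightrange

Analysis pipeline for quantifying artificial light at night (ALAN) within
species' geographic ranges, from a multi-year stack of nighttime-light
composites (digital numbers 0–63) and a set of range polygons:

1. **synthetic** — generates nightscape stacks (urban cores saturating at
   DN 63, radially decaying fringes, secular growth in lit area), per-year
   quadratic sensor distortions, and elliptical species ranges with exact
   ground-truth pixel masks.
2. **grids** — raster I/O (single-band GeoTIFF-tagged TIFF), GeoJSON range
   I/O, the shared equal-area grid, and pixel-center rasterization of range
   polygons (centroid fallback guarantees every range ≥ 1 pixel).
3. **calibration** — intercalibrates every year onto a reference year's DN
   scale with a second-order polynomial fitted by quantile regression through
   the median (exact L1 solution via linear programming), using co-lit
   "stable" pixels with optional MAD trimming.
4. **exposure** — lit classification (dark ⇔ DN < 5.5), per-year and
   period-mean lit fractions, mean/summed DN, and the evenness statistic
   (smallest fraction of range pixels contributing 95% of cumulative DN).
5. **trends** — Mann-Kendall trend test from first principles (tie-corrected
   variance, tau-b, continuity-corrected z; exact small-n option), per
   species and on the across-species mean lit-pixel series.
6. **richness** — species-richness and threatened-richness grids, equal-width
   richness classes, and the richness–brightness Pearson correlation with
   Fisher-z confidence intervals (per richness level, or per pixel).
7. **groups** — used vs not-used comparison: one-way two-group linear model
   on arcsine-square-root-transformed lit proportions.
8. **pipeline / cli** — orchestration from a config with reproducible seeds,
   writing tidy CSV/JSON outputs and a run manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the oracle-equivalence and
simulation-calibration checks (Mann-Kendall vs exhaustive pair enumeration,
evenness vs a sort-and-accumulate oracle, rasterization vs exhaustive
pixel-center point-in-polygon, L1 coefficient recovery under injected
distortion, type-I/power calibration, and the end-to-end directional run on
the default synthetic bundle).

## CLI

```sh
nightrange run --seed 1 --outdir out          # full pipeline, default synthetic bundle
nightrange run --config cfg.yaml              # or from a YAML/JSON config
nightrange simulate --outdir bundle --seed 3  # export a synthetic bundle
nightrange calibrate bundle/observed/*.tif --outdir cal
nightrange exposure cal/calibrated_*.tif --ranges bundle/ranges.geojson \
    --periods 1992-1996,2008-2012 --out exposure.csv
nightrange trend series.csv --out trends.csv  # CSV of (series_id, year, value)
nightrange richness cal/calibrated_*.tif --ranges bundle/ranges.geojson --out rich.json
nightrange compare-use exposure.csv --ranges bundle/ranges.geojson --out use.json
```

Pipeline outputs (under `--outdir`): `exposure.csv`, `evenness.csv`,
`trends.csv`, `trend_summary.json`, `richness_correlations.csv`,
`richness_levels_{all,threatened}.csv`, `table1_analog.csv`,
`use_comparison.json`, `calibration_model.json`, `manifest.json`.

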