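# agroniche

Forage germplasm performance evaluation and introduction-adaptability
prediction, exercised end-to-end on synthetic data with known ground truth.

The package covers two linked workflows:

1. **Field-trial evaluation** — descriptive/variation statistics with
   leaf-area correction and Shannon trait diversity (`traits`),
   entropy-weighted grey relational analysis, PCA trait-contribution
   screening, fuzzy membership comprehensive scoring and hierarchical
   cluster cuts (`scoring`), and ridge-regression path analysis
   decomposing trait–yield correlations into direct and indirect effects
   (`path_analysis`).
2. **Niche modelling & adaptability** — occurrence cleaning and grid
   rarefaction, collinearity filtering, pseudo-absence generation, an
   AUC-thresholded AUC-weighted ensemble of five learner families with
   TSS/Kappa/AUC evaluation and permutation variable importance (`sdm`);
   Fisher–Jenks suitability classification, spherical area accounting,
   zonal summaries and great-circle centroid migration (`geo`); and
   region-profile extraction, optimal-dissimilarity screening, Mantel
   permutation tests and a germplasm × region adaptability matrix
   (`adaptability`).

Synthetic inputs (replicated trait tables driven by a latent yield axis,
smooth environmental landscapes with a known logistic suitability surface,
presence points, mock region polygons) come from `simulate`; raster
(ESRI ASCII grid), stack-manifest and GeoJSON I/O live in `grids`; the
seeded, restartable pipeline driver is `pipeline`.

## CLI

```bash
# full demo pipeline (synthetic data, seeded, byte-reproducible)
agroniche run --seed 1 --outdir out/

# individual stages
agroniche simulate --seed 1 --outdir out/
agroniche traits --table out/simulate/traits.csv --outdir out/traits
agroniche score  --table out/simulate/traits.csv --outdir out/score
agroniche path   --table out/simulate/traits.csv --target HY --outdir out/path
agroniche sdm fit --occ out/simulate/occurrences.csv --env out/simulate/env_current \
    --repeats 10 --train-fraction 0.75 --auc-threshold 0.75 --seed 1 --outdir out/sdm
agroniche geo classify --raster out/sdm/consensus.asc --out out/class.asc
agroniche geo areas --classmap out/class.asc --regions out/simulate/regions.geojson \
    --out out/areas.csv
agroniche geo centroid-shift --classmap1 a.asc --classmap2 b.asc --out shift.json
agroniche adapt score --traits out/simulate/traits.csv --suit out/sdm/consensus.asc \
    --env out/sdm/env_filtered --regions out/simulate/regions.geojson \
    --trial-lon 95 --trial-lat 32 --outdir out/adapt
```

`agroniche run --config cfg.yaml` accepts a YAML overriding any key of the
default configuration (see `pipeline.default_config`); every random stage is
seeded and a rerun with the same config is byte-identical.

## Notes

- All artifacts are plain text (CSV, JSON, YAML, `.asc` rasters, GeoJSON) so
  runs can be diffed without binary tooling.
- Rasters follow the ESRI ASCII grid convention; values written with `%.17g`
  round-trip float64 bit-exactly.
- The trait-diversity index is the sum of per-trait replicate Shannon
  indices; CV uses the sample (n−1) standard deviation.
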