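# phenocube

Occurrence mapping of invasive buffel grass (*Cenchrus ciliaris*) from
multi-year vegetation-index time series, implemented as a tested, reusable
Python pipeline.

Buffel grass is an introduced pastoral grass that now dominates large parts
of arid Australia and threatens dryland ecosystems worldwide. Managing it
requires maps of where it actually grows, at a resolution finer than any
existing survey. Single-date spectral classification struggles because dry
buffel looks like any other dry grass; what is distinctive is its
*phenology* — after rain it greens up faster, peaks higher and stays green
longer than native arid grasses. `phenocube` turns that temporal signature
into per-pixel occurrence probabilities:

1. **Data cube → index matrices.** A dated stack of 5-band surface
   reflectance (BLUE, GREEN, RED, NIR, SWIR1) is screened per acquisition
   (strictly < 3% cloud and > 90% valid data), four vegetation indices are
   computed —

   EVI = G·(NIR − RED)/(NIR + C1·RED − C2·BLUE + L) with G = 2.5, C1 = 6,
   C2 = 7.5, L = 1; NBR = (NIR − SWIR1)/(NIR + SWIR1);
   NDVI = (NIR − RED)/(NIR + RED); NDWI = (GREEN − NIR)/(GREEN + NIR)

   — and each index cube is reshaped to a matrix **M** with rows =
   acquisition dates and columns = pixels.
2. **SVD temporal features.** The truncated SVD **M** ≈ **U Σ Vᵀ** separates
   temporal modes (columns of **U**) from spatial loadings (rows of
   **Vᵀ**). The six leading spatial loadings of each index — 24 values per
   pixel — summarise each pixel's phenological history.
3. **Stepwise-BIC logistic regression.** Against field waypoints labelled
   buffel / buffel-free, a forward stepwise logistic regression guided by
   the Bayesian Information Criterion selects a parsimonious feature subset;
   a one-hidden-layer (3 tanh nodes) neural network serves as a
   nonlinearity check. Models are evaluated over ten stratified 2/3–1/3
   train/validation splits (sensitivity, specificity, accuracy, ROC-AUC,
   mean ± SE).
4. **Probability map.** P(buffel) = 1/(1 + e^(−(β₀ + Σ βᵢxᵢ))) per pixel,
   thresholded occurrence maps, and per-landscape-stratum p50/p75 area
   fractions and accuracies.

Because the field waypoints and full satellite archives behind such studies
are not redistributable, the package ships a first-class synthetic-scene
generator (`synthetic_scene`) that emulates the statistical structure the
method relies on — rainfall-pulse phenology with the buffel contrast, fire
events that depress NBR, cloud/nodata dropout, a blocky land-cover mosaic
with landscape strata — so every stage is testable end to end.

## Worked example

```python
import phenocube as pc

config = pc.default_benchmark_config(seed=42)     # 64x64 px, 2016-2025
scene = pc.build_scene(config)
waypoints = pc.sample_waypoints(scene, 400, stratified=True, seed=43)
result = pc.full_pipeline(scene, waypoints)

print("retained mosaics:", result["matrices"]["NDVI"].values.shape[0])
print("selected features:", result["model"].selected_features)
for m, (mean, se) in result["report"].metrics["validation"].items():
    print(f"validation {m}: {mean:.3f} +/- {se:.3f}")
print(result["strata_summary"][["name", "pixels", "p50", "p75"]].round(3))
```

prints

```
retained mosaics: 167
selected features: ['ndvi_2']
validation sensitivity: 0.990 +/- 0.005
validation specificity: 1.000 +/- 0.000
validation accuracy: 0.997 +/- 0.002
validation auc: 1.000 +/- 0.000
          name  pixels   p50   p75
alluvial_plain    1664 0.486 0.486
 granite_range    1408 0.294 0.293
     dunefield    1024 0.019 0.018
```

Of 202 simulated acquisitions, 167 mosaics survive the cloud/validity
screen. On this scene a single NDVI spatial loading already separates the
classes, so stepwise selection stops after one feature, and the bootstrap
validation accuracy is ~99.7%. The stratum table shows the mapped
occurrence structure: roughly half of the buffel-rich alluvial plain
exceeds P ≥ 0.5, versus ~2% of the buffel-free dunefield.

The same pipeline runs from the shell, stage by stage, with provenance
sidecars and re-entrant outputs:

```sh
phenocube simulate  --config run.yaml
phenocube indices   --config run.yaml
phenocube decompose --config run.yaml
phenocube fit       --config run.yaml
phenocube evaluate  --config run.yaml
phenocube map       --config run.yaml
phenocube report    --config run.yaml
```

`run.yaml` is a flat key/value document (see
`phenocube.cli_io.PipelineConfig`); every stage accepts `--seed` and
`--force`.

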