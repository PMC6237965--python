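# coldsoil

Analysis pipeline for studying "cold soil in a warm world" effects in
seasonally snow-covered forests:

- **Sensor pipeline** — hourly soil-temperature (T_S), air-temperature (T_A)
  and relative-humidity loggers are reduced to daily summaries; snow presence
  is detected from the daily T_S range (ΔT_S ≤ 1 °C over two consecutive days
  and daily max T_S < 2 °C), aggregated to plot level by a ≥50 % sensor
  quorum, and summarised into snow seasons (SCD_ST), freeze–thaw-event counts
  (days with mean T_S ≤ −5 °C) and seasonal statistics.
- **Proxy years** — monthly temperature anomalies against a 1961–1990
  baseline climatology, polynomial trend fitting, and robust (trimmed-means
  Welch) selection of a baseline and a warm proxy study year (Dec–Nov).
- **Fusion** — STARFM-style weighted-neighbourhood prediction of fine-scale
  reflectance scenes on coarse-only dates from 1–2 same-day coarse/fine
  pairs, with nearest-neighbour resampling, QA masking, and Spearman-ρ /
  RMSE / MAE accuracy assessment.
- **Snow mapping** — NDSI/NDVI computation, period-specific NDSI thresholds
  with the NDVI auxiliary rule, green-band floor masking, and plot-level
  daily snow flags (SCD_S) from a 15-m buffer around each plot center.
- **Comparison** — k-means (k = 3) site classification from LAI,
  year × site linear mixed-effects contrasts with sensor-nested-in-plot
  random intercepts, and SCD_ST vs SCD_S confusion-matrix agreement.
- **Synthetic data** — seeded generators for full sensor campaigns, raster
  scene series and anomaly records with known ground truth (snow seasons,
  per-pixel snow masks, injected warm-year anomalies), used throughout the
  test suite for recovery testing.

Rasters use four reflectance bands (green, red, NIR, SWIR2) stored as
reflectance × 10⁴ in signed 16-bit with nodata −9999 plus a boolean QA band,
serialised as a flat row-major `.i16` binary with a `.json` geometry sidecar.

## CLI

```sh
coldsoil simulate --config cfg.yaml --seed 1 --out sim/      # campaign CSVs
coldsoil sensors  --in sim/sensors.csv --out tables/         # flags/seasons/FTE/stats
coldsoil proxy    --local local.csv --reference ref.csv --years 2014,2015,2016,2017
coldsoil fuse     --pair1-fine f1 --pair1-coarse c1 --coarse-tp ctp --out pred
coldsoil snowmap  --scene pred --plots plots.csv --out flags.csv
coldsoil run      --config experiment.yaml --seed 1 --out report/
```

`coldsoil run` executes the full synthetic experiment
(simulate → sensors → proxy → fuse → snowmap → compare) and writes
`report.json` plus tidy CSV tables. The experiment YAML has optional
`campaign:`, `scene:`, `anomaly:` and `options:` sections whose keys mirror
`CampaignConfig`, `SceneConfig`, `AnomalyConfig` and `ExperimentConfig`.

## Layout

```
src/coldsoil/
  synthetic.py   # campaign / scene / anomaly generators + ground truth
  sensors.py     # daily summaries, snow detection, seasons, FTEs, stats
  proxy.py       # anomalies, trend fit, proxy-year selection
  fusion.py      # scene preparation, resampling, STARFM prediction, accuracy
  snowmap.py     # NDSI/NDVI, classification, plot extraction
  compare.py     # site classes, mixed-model contrasts, agreement
  pipeline.py    # end-to-end experiment orchestration
  rasters.py     # scene model + flat-binary I/O
  io.py          # sensor/truth/monthly CSV interchange
  cli.py         # click entry points
```
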