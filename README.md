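# aeropath

Flight-efficiency analysis for songbird migration tracked with an automated
VHF telemetry array. The package reconstructs flight segments from raw
detection tables, annotates them with tailwind/crosswind components from
layered wind fields, "probes the atmosphere" by selecting the wind altitude
whose model best explains flight duration (AICc scan), and fits multilevel
piecewise path models (Fisher's C over d-separation basis sets, path AICc,
Akaike weights, backward elimination) relating age, flight stage, and winds
to flight duration and groundspeed. A seeded simulator generates synthetic
datasets — station array, lattice wind fields, departure behaviour,
wind-triangle flights, signal-strength detection curves — with ground truth
for recovery testing.

## Layout

| module | role |
| --- | --- |
| `aeropath.geometry` | spherical-Earth haversine/bearing/destination/midpoint |
| `aeropath.telemetry` | detection series, pulse-rate filter, peak events, crossing classification, flight segments |
| `aeropath.wind` | wind components, space–time IDW interpolation, per-level segment annotation |
| `aeropath.mixedlm` | maximum-likelihood linear mixed models (random intercepts, possibly crossed) |
| `aeropath.altitude` | per-level all-subsets AICc wind models and the cross-altitude scan |
| `aeropath.pathmodel` | path DAGs, basis sets, Fisher's C, path AICc, weights, backward elimination |
| `aeropath.simulate` | seeded synthetic datasets and lightweight statistical generators |
| `aeropath.pipeline` / `aeropath.io` / `aeropath.cli` | orchestration, CSV/YAML I/O, command line |

## Command line

```bash
# generate a synthetic dataset (stations.yaml, winds.csv, detections.csv, birds.csv, truth.csv)
aeropath simulate --seed 1 --outdir data/

# step by step
aeropath reconstruct --stations data/stations.yaml --detections data/detections.csv \
    --metadata data/birds.csv --out segments.csv
aeropath annotate --segments segments.csv --winds data/winds.csv --out annotations.csv
aeropath probe --segments segments.csv --annotations annotations.csv --stage ocean --out scan.csv
aeropath pathfit --table analysis.csv --response flight_duration --out selection.csv

# or everything at once from a YAML config (see aeropath.pipeline.PipelineConfig)
aeropath run --config pipeline.yaml
```

The full run writes segments, per-level annotations, altitude-scan tables and
a ΔAICc-vs-altitude plot, model-selection tables (equations, K, AICc, ΔAICc,
W, cumulative W, Fisher's C), standardized coefficient tables, and a JSON run
log with the seed and every analysis setting.

## Conventions

- Coordinates are decimal degrees (west negative); bearings degrees clockwise
  from geographic north; timestamps UTC (ISO-8601 in files, epoch seconds in
  memory); distances km on a 6371.0 km sphere.
- Wind directions are stored in the direction-to convention; files may
  declare `dir_convention: from` per row and are converted on read.
- All model comparison uses maximum-likelihood (never REML) fits so AICc is
  comparable across fixed-effect structures; `k` counts fixed effects,
  random-intercept variances, and the residual variance.
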