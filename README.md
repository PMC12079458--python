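# aggrekin

Single-aggregate analysis of protein-aggregation kinetics from
time-resolved super-resolution localization microscopy, plus the bulk
assays that accompany it. The package covers the full workflow:

- **`aggrekin.simulate`** — ground-truth-labeled synthetic acquisitions:
  sparse binding events accumulating on growing aggregate footprints
  (anisotropic two-phase, isotropic, and terminating small-aggregate
  archetypes), false positives, stage drift, and sigmoidal turbidity
  curves parameterised by their tangent lag time.
- **`aggrekin.locio`** — localization-table CSV I/O (ThunderSTORM-style
  and generic dialects) and reconstruction rendering.
- **`aggrekin.preprocess`** — intensity filtering (automatic Otsu
  threshold on log intensity) and drift correction by cross-correlation
  of time-binned reconstructions.
- **`aggrekin.segment`** — incremental spatiotemporal clustering that
  assigns each localization to an individual aggregate, dissects
  touching/intertwined structures along their temporal pathways, and
  scores assignments against ground truth.
- **`aggrekin.morphology`** — occupancy-grid area curves, covariance
  axis ratios, and classification into anisotropic / isotropic / small
  (final area below 10 µm²).
- **`aggrekin.kinetics`** — growth-rate fitting: single-phase OLS,
  continuous two-segment piecewise fits with exhaustive changepoint
  search, termination detection, condition summaries (mean ± SE) and
  Welch t-tests.
- **`aggrekin.turbidity`** — baseline–tangent lag-phase estimation and
  condition comparisons.
- **`aggrekin.abundance`** — aggregate-type count tables and integer
  small-aggregate percentages.

All quantities use nm / nm² / seconds internally; areas are reported in
nm² and µm², rates in nm²/s, lag phases in minutes.

## Command-line interface

The `aggrekin` entry point exposes the pipeline stages:

```sh
# synthetic demo field of view + ground-truth sidecar
aggrekin simulate --seed 1 --out locs.csv --truth-out truth.csv

# generic CSV -> canonical localization dialect
aggrekin convert generic.csv locs.csv --column-map '{"f":"frame","xpos":"x_nm","ypos":"y_nm","photons":"intensity"}'

# filter, drift-correct, segment
aggrekin segment locs.csv --assignments-out assign.csv --summary-out clusters.csv

# classify aggregates and fit growth rates
aggrekin fit locs.csv assign.csv --rates-out rates.csv --summary-out condition.csv

# turbidity lag phases and Welch tests vs control
aggrekin lag turbidity.csv --out lags.csv --control control

# abundance statistics from per-image counts
aggrekin abundance counts.csv --out table.csv
```

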