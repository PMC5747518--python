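# stopgo

Analysis pipeline for stop-and-go T-cell motility and ratiometric
(green-indicator / red-anchor) calcium imaging: track-derived motility
statistics, bleach-corrected normalized Ca²⁺ ratio traces, spatiotemporal
Ca²⁺-transient detection in XY-T image stacks, Ca²⁺-rise-triggered velocity
averaging, and nonparametric group comparison — plus a synthetic-data
module that generates tracks, coupled calcium traces, and rendered
two-channel image stacks with full ground truth.

## Modules

| module | purpose |
| --- | --- |
| `stopgo.synthetic` | two-state persistent-random-walk simulator, calcium trace synthesis, image-stack rendering, all with ground truth |
| `stopgo.motility` | instantaneous velocity, arrest coefficient, pause durations, CoV, turn angles, directionality-ratio decay (fitted τ), MSD and motility coefficient, velocity histograms |
| `stopgo.ratio` | linear photobleach correction, G/R ratio, R/R₀ normalization, elevated/basal classification, quadrant fractions, state-conditional velocity |
| `stopgo.detect` | autofluorescence masking, connected-component transient detection in (T, Y, X) with voxel/duration filters, ellipsoid metrics, sparkle vs cell-wide classification, event statistics |
| `stopgo.coupling` | ratio-rise onset detection, event-triggered velocity averaging, velocity–ratio Spearman scatter |
| `stopgo.stats` | Mann–Whitney U (exact/asymptotic), Hodges–Lehmann estimate + CI, group summary tables |
| `stopgo.io` / `stopgo.pipeline` / `stopgo.cli` | track CSV, two-channel TIFF, YAML config, manifest, end-to-end driver |

## CLI

```bash
stopgo simulate --n-cells 50 --duration-s 600 --out tracks.csv
stopgo motility tracks.csv --out motility_summary.csv
stopgo calcium tracks.csv --out ratio_traces.csv
stopgo couple tracks.csv --out aligned_average.csv
stopgo detect stack.tif --pixel-um 0.65 --dt-s 0.5 --out events.csv
stopgo compare motility_summary.csv --metric arrest_coefficient --label group
stopgo run config.yaml --out-dir out/
```

Track CSV schema: `cell_id, frame, t_s, x_um, y_um[, z_um][, green, red]`
(µm, seconds; velocities are reported in µm/min). TIFF stacks are
multi-page, channel-interleaved (green, red per frame), with pixel size
and frame interval stored in the image description (overridable with
`--pixel-um` / `--dt-s`).

## Conventions

- Instantaneous velocity from consecutive frames, no smoothing; mean track
  velocity is the mean of instantaneous velocities.
- Arrest: fraction of steps strictly below 2 µm/min; slow-cell fraction
  strictly below 7 µm/min; elevated Ca²⁺ strictly above 1.10 normalized
  ratio; fast/slow split strictly at 10 µm/min.
- Bleach correction divides the red trace by its own normalized fitted
  linear trend (per cell, multiplicative model).
- Transient filters: components must exceed 10 voxels (strict) and last
  ≥ 2 s (inclusive frame extent); connectivity is full 26-neighborhood
  with time as the third axis.
- MSD uses overlapping windows; the motility coefficient M is
  slope / (2·dim) from a zero-intercept fit over the first quarter of lags.

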