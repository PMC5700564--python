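# piipath

Behavioral segmentation of GPS telemetry for caching foragers.

Caching predators revisit kill/cache sites over days, interleaving feeding
with rests away from the cache. Step length and turn angle alone miss this
structure, so `piipath` combines four per-fix metrics — speed, absolute
turning, a straightness (out-and-back recursion) index, and a
spatiotemporal site-fidelity index — into a composite movement index on
[0, 4]. The index is smoothed with a centered moving average whose width
comes from the first zero crossing of its autocorrelation function (the
path identification index, PII), and each fix is classified as **directed**
(PII < 1.4), **search** (1.4–1.8), or **cache/denning** (PII > 1.8).
The package also:

- evaluates classifications against field-verified sites (per-animal and
  pooled confusion tables with whole-percent accuracy),
- fits paired use-versus-availability logistic step-selection models per
  circadian x behavior subset (9 per animal) to expose nonstationary
  selection, and
- ships a seeded semi-Markov caching-forager simulator (with rest
  excursions, fix failures, synthetic exposure rasters, and optional
  covariate-coupled steps) so the whole pipeline is testable without
  collar data.

## Data formats

- **Fix tables**: delimited text with a header; columns animal id,
  timestamp (local standard time, ISO 8601), projected planar x/y in
  meters, optional validity flag. Column names are remappable
  (`column_map`). Geographic-looking coordinate columns are refused —
  project first. On read each animal is placed on the nominal acquisition
  grid (default 240 min); missed slots become invalid placeholders so fix
  success rates are accountable.
- **Verification tables**: delimited text with animal id, a seq or
  timestamp reference, and an observed class (`cache` / `non_feeding`).
- **Rasters**: single-band ESRI ASCII grid (`.asc`) in the same projected
  meters as the fixes.

## CLI

```sh
piipath simulate  --seed 1 --days 180 --out-dir data/        # synthetic bundle
piipath metrics   --fixes data/fixes.csv --out-dir out/      # four metrics + scaling
piipath pii       --fixes data/fixes.csv --out-dir out/ --paper-mode
piipath evaluate  --labels out/SIM01_labels.csv --truth truth.csv --out confusion.csv
piipath stepselect --fixes data/fixes.csv --labels out/SIM01_labels.csv \
                   --raster data/raster.asc --out-dir out/
```

`--paper-mode` applies the reference defaults in one flag: 100 m fidelity
radius, +/- 8 week fidelity window, fixed 15-fix smoothing window
(2.5 days at 4-h fixes), and 1.4/1.8 thresholds. Without it the smoothing
window is selected per animal from the ACF. Logs go to stderr; data only
to files.

## Library sketch

```python
import piipath as pp

sim = pp.simulate(pp.SimConfig(seed=1, duration_days=180))
metrics = pp.compute_metrics(sim.trajectory)
constants = pp.compute_scaling(metrics, sim.trajectory.animal_id)
index = pp.standardize(metrics, constants)["index"].to_numpy()
window = pp.select_window(pp.acf(index, max_lag=60))   # or override=15
labels = pp.classify(pp.smooth(index, window).pii)
segments = pp.segment(labels, sim.trajectory.animal_id)
```

## Scope notes

- The topographic-exposure covariate is an input raster; computing it from
  elevation models is out of scope.
- GeoTIFF raster input is not supported (no GDAL stack in the target
  environment); use ESRI ASCII grids.
- Thresholds and all scaling parameters are configuration, not fitted
  quantities; there is no probabilistic (hidden-Markov) state assignment.
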