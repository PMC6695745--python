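# accelcal

Energy-expenditure-referenced calibration of raw triaxial accelerometry, and
free-living physical-activity intensity classification built on it.

The pipeline has two halves:

1. **Lab calibration.** Raw hip/thigh acceleration recorded during a seated
   rest + stand + treadmill protocol (walks at 3/4/5/6 km/h, runs at 8/10 km/h)
   is down-sampled to 30 Hz, truncated to ±6 g, band-pass filtered
   (0.29–10 Hz, zero phase) and aggregated to an mg (milli-g) intensity
   metric. Oxygen uptake gives the criterion measures: resting VO2 (minimum
   2-min moving average of the 20-min rest), MET (gross/resting), net VO2
   ((gross − standing)/weight, mL·min⁻¹·kg⁻¹) and the dimensionless
   equivalent speed V²/(g·h). Adult MET cut-points (1.5/3.0/6.0/9.0) are
   translated to net-VO2 cut-points by linear regression; anchored monotone
   smoothing splines of criterion vs mg are inverted per age group and
   placement into integer mg cut-point tables for both calibration routes.
   Because the net-VO2 cut-points are defined from the adult MET values, the
   two routes coincide exactly for adults by construction.
2. **Free-living classification.** 3-s epoch series are cleaned (explicit
   non-wear flags, or ≥60-min runs of all-axis SD < 3 mg; epochs starting in
   23:00–06:00 removed), classified against the cut-point table (closed on
   the left), and summarized into per-day minutes/% per level (SED/LPA/MPA/
   VPA/VVPA; valid day ≥ 720 wear minutes) and per-age-category means
   (children <13, adolescents 13–16, adults <50, adults ≥50).
   MVPA = MPA + VPA + VVPA.

A first-class synthetic-data module generates both study halves with known
ground truth (closed-form mg cut-points, planted free-living states), so the
whole pipeline is testable end to end without any device recordings.

Note: the published summary table this package ships as reference data sums
older adults' MET-calibrated MVPA to 71 min/d while the source abstract
prints 41 min/d; the table is taken as authoritative.

## CLI

```bash
# synthetic datasets (lab CSVs, free-living epoch CSVs, ground_truth.json)
accelcal simulate --seed 1 --out data/ [--subjects N] [--days D] [--kind lab|freeliving|both]

# lab calibration: cut-point table (JSON + CSV) from a directory of
# subjects.csv, {sid}_hip.csv, {sid}_thigh.csv, {sid}_vo2.csv
accelcal calibrate --data data/lab --out results/cal

# free-living classification under both calibration routes
accelcal classify --data data/freeliving --cutpoints results/cal/cutpoints.json --out results/fl

# re-aggregate a per-day CSV into a group summary
accelcal summarize --days results/fl/days_vo2net.csv --subjects data/freeliving/subjects.csv --out summary.csv
```

All commands take `--config config.yaml` overriding the defaults in
`accelcal.io_cli.RunConfig` (band, rates, epoch length, MET cut-points,
non-wear/night/valid-day rules, fitting switches). Exit codes: 0 success,
2 configuration error, 3 data error. Every output embeds the resolved
configuration (JSON) or a config digest (CSV comment line).

File formats (CSV throughout; proprietary device binaries are out of scope):

- raw: `time,x,y,z` — ISO-8601 or elapsed-seconds time, accelerations in g
- VO2: `time_s,vo2_ml_min,stage` with stage ∈ rest/stand/walk3…run10
- subjects: `subject_id,age,group,height_m,weight_kg[,sex]`
- epochs: `epoch_start,mg,wear[,nonwear]`

## Python API

```python
from accelcal.io_cli import RunConfig, run_calibration_pipeline, run_freeliving_pipeline

config = RunConfig()
table, report = run_calibration_pipeline("data/lab", config, out_dir="results/cal")
summaries = run_freeliving_pipeline("data/freeliving", table, config, out_dir="results/fl")
```

Modules: `signal_processing` (resample/truncate/band-pass/epoch mg + ENMO),
`physiology` (REE, MET, net VO2, equivalent speed), `calibration` (regression,
anchored splines, cut-point tables), `free_living` (non-wear, night window,
classification, summaries), `synthetic_data` (generator + analytic ground
truth), `io_cli` (formats, config, pipelines, CLI), `published` (reference
cut-points and summary tables).

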