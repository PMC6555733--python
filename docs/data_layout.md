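# Dataset layout

A dataset is a directory tree with one leaf directory per subject and
condition:

```
root/
  <subject_id>/
    <condition_id>/
      signals.csv
      breaths.csv
      meta.json
  ground_truth.json      # optional, written by the synthetic generator
  manifest.json          # optional, written by the CLI
```

## signals.csv

RFC-4180 CSV with a header row naming the channels, one column per channel,
one row per sample.  All channels share the sampling rate and length given
in `meta.json`.  Values are serialized with 17 significant digits so they
round-trip in full double precision.

Channel names follow `<kind>_<side>_<axis|muscle>`:

| part | values |
| ---- | ------ |
| kind | `grf` (ground reaction force, N) or `emg` (arbitrary units) |
| side | `r` or `l` |
| axis / muscle | `x`/`y`/`z` for forces; a muscle name for EMG |

Every trial must contain `grf_r_z` (right vertical GRF); it drives
gait-cycle segmentation.

## breaths.csv

Columns `time,vo2,vco2`: breath timestamp (s, strictly increasing), V̇O2
and V̇CO2 (L/min, non-negative).

## meta.json

```json
{
 "subject": {"subject_id": "S00", "mass": 77.5, "leg_length": 0.89},
 "condition": {
  "condition_id": "assist04",
  "incline_grade": 0.0,
  "load_fraction": 0.0,
  "assistance_work": 0.0,
  "is_baseline_normal_walk": true
 },
 "sampling_rate": 2000.0
}
```

`mass` is in kg (> 0), `incline_grade` and `load_fraction` are fractions,
`assistance_work` is J per gait cycle.  Exactly one condition per subject
has `is_baseline_normal_walk: true`; its trial provides the per-muscle EMG
normalization maxima.
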