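# File formats

All on-disk artifacts are plain CSV and JSON. Conventions:

- **Times** are milliseconds from recording start, 0-based.
- **Positions** are millimetres in a paw-centered frame.
- **Rates** are spikes per second; **conductances** nanosiemens;
  **potentials** millivolts; **currents** picoamperes; **forces** grams.
- CSV files carry a header row. Round-trips are lossless for the
  declared columns; readers ignore (and writers never drop) columns they
  do not know.

## Spike table (`spikes.csv`, `afferent_spikes.csv`)

One row per spike.

| column    | type   | description                              |
|-----------|--------|------------------------------------------|
| `unit_id` | string | unit (or afferent) identifier            |
| `t_ms`    | float  | spike time, ms, ≥ 0                      |

Rows are sorted by time within each unit on write; unsorted input is
accepted and sorted on load. Non-numeric, non-finite or negative times
are rejected with the offending line numbers (1-based, counting the
header line).

## Dataset directory

A synthetic recording session is a directory with these files (all
required by `load_dataset`; missing files are enumerated in the error):

```
units.csv  afferents.csv  stimuli.csv  spikes.csv  afferent_spikes.csv
conditions.csv  ground_truth.json  config.json
```

### `units.csv`

One row per recorded spinal unit.

| column                | type   | description                                     |
|-----------------------|--------|-------------------------------------------------|
| `unit_id`             | string | unique unit identifier                          |
| `cell_class`          | string | `adapting` or `non_adapting`                    |
| `depth_um`            | float  | recording depth below the dorsal surface, µm    |
| `spont_rate_baseline` | float  | baseline spontaneous rate, spk/s                |
| `tau_class_ms`        | float  | generator adaptation constant; empty = flat (∞) |
| `A_En`,`w_En`         | float  | narrow excitatory RF component (nS, mm)         |
| `A_Eb`,`w_Eb`         | float  | broad excitatory RF component (nS, mm)          |
| `A_I`,`w_I`           | float  | inhibitory RF component (nS, mm)                |
| `theta`               | float  | RF drive threshold (nS)                         |
| `center_x_mm`,`center_y_mm` | float | RF center position                        |

### `afferents.csv`

One row per afferent-to-unit connection; unconnected afferents get one
row with the connection columns empty.

| column              | type   | description                          |
|---------------------|--------|--------------------------------------|
| `afferent_id`       | string | unique afferent identifier           |
| `kind`              | string | `RA` (rapidly adapting) or `SA`      |
| `center_x_mm`,`center_y_mm` | float | afferent RF center            |
| `connected_unit_id` | string | target unit (empty if none)          |
| `probability`       | float  | per-spike transmission probability   |
| `latency_ms`        | float  | synaptic latency, ms (> 0)           |

### `stimuli.csv`

One row per 1 s stimulus application.

| column          | type   | description                                |
|-----------------|--------|--------------------------------------------|
| `stim_id`       | string | unique stimulus identifier                 |
| `kind`          | string | `brush` or `vf` (von Frey)                 |
| `position_x_mm`,`position_y_mm` | float | stimulation site           |
| `onset_ms`      | float  | application onset                          |
| `duration_ms`   | float  | application length (1000 by protocol)      |
| `force_g`       | float  | von Frey force in grams; empty for brush   |
| `zone`          | string | `center`, `surround` or `costim`           |

### `conditions.csv`

One row per condition epoch; epochs tile the recording.

| column      | type   | description                                       |
|-------------|--------|---------------------------------------------------|
| `condition` | string | `baseline`, `kcc2_block`, `bdnf`, `bdnf_actz`, `glycine_block` |
| `start_ms`  | float  | epoch start (inclusive)                           |
| `end_ms`    | float  | epoch end (exclusive)                             |

### `ground_truth.json`

Generator ground truth, one JSON object:

- `classes`: `{unit_id: cell_class}`
- `tau_class_ms`: `{unit_id: float|null}` (`null` = flat)
- `spont_rate_baseline`: `{unit_id: spk/s}`
- `depth_um`: `{unit_id: µm}`
- `connections`: list of `{afferent_id, unit_id, probability, latency_ms}`
- `epochs`: list of `{condition, start_ms, end_ms}`
- `E_inh_per_epoch`: `{condition: mV}`
- `backend`: `rate` or `mechanistic`
- `master_seed`: int
- `duration_ms`: total recording length

### `config.json`

The `DatasetConfig` used for generation, serialized field-by-field
(see `dorsalhorn.synthetic_recordings.DatasetConfig`). Together with
`master_seed` it reproduces the dataset bit-for-bit.

## Analysis outputs

### `unit_summary.csv` (from `analyze-dataset`)

One row per unit: `unit_id`, `depth_um`, `tau_ms` (fitted adaptation
constant), `class_recovered`, `low_spike_count` (fewer than 10 pooled
spikes under the classification stimuli — the fit is reported but
flagged), `class_true` (empty without ground truth), then per condition
`spont_<condition>` and `evoked_<condition>` (spk/s; evoked = mean
stimulus-window rate − spontaneous rate of the epoch's quiet period).

### `recovery.json` (from `analyze-dataset`)

`n_units`, `n_afferents`, `class_accuracy` (fraction of ground-truth
labels recovered), `n_unclassified`, `connections`
(`n_pairs_tested`, `n_true`, `true_positive_rate`, `false_positives`,
`flagged` pair list with correlogram peak lag/probability) and the
`per_unit` rows. Note that `false_positives` counts flagged pairs that
share stimulus drive but no synapse; the correlogram criterion cannot
distinguish tight stimulus co-modulation from connectivity, so this
number is informative, not an error rate for independent pairs.

### i-o curve (`io_curve.csv` from `simulate-io`)

| column      | type  | description                         |
|-------------|-------|-------------------------------------|
| `g_exc0_nS` | float | mean excitatory conductance         |
| `rate_hz`   | float | mean firing rate across trials      |
| `sem`       | float | standard error of the mean          |

with `io_summary.json` holding `slope_hz_per_nS`, `intercept_hz`,
`spont_rate_hz`, `r_squared` and the run parameters.

### Summary report (`reproduce-summary`)

`io_matrix.csv` (cell × alpha × E_inh with slope/intercept/spontaneous
rate), `costim_ratios.csv` (cell class × condition co-stimulation
ratios), `zone_drives.csv` (RF zone areas and drives per class and
condition) and `summary.json` (all tables plus the `checks` map and
`failures` list; the command exits nonzero if any check fails).
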