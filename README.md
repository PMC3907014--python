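# gaitbci

EEG idling/walking kinesthetic-motor-imagery decoding toolkit: offline model
training, online sliding-window decoding through a dual-threshold state
machine, session performance metrics, an autoregressive Monte-Carlo
significance control, EMG/gyroscope movement validation, and a synthetic-data
generator so everything is testable without recordings.

## What it does

- **`gaitbci.io_signals`** — recording/cue data model, plain-EDF and
  delimited-matrix I/O, robust (median/MAD z of log-variance and kurtosis)
  artifact-channel exclusion, cue-locked epoching, and band-power features
  (single Hamming periodogram per 0.75-s window, integrated over half-open
  2-Hz bins).
- **`gaitbci.prediction_model`** — offline training: per-class PCA subspaces
  with a minimum-reconstruction-error piecewise assignment, a 1-D
  information-theoretic discriminant (Fisher-LDA fallback), a linear
  Bayesian classifier on the scalar feature, stratified 10-fold
  cross-validation, and greedy 2-Hz-grid frequency-band optimization.
- **`gaitbci.online_decoder`** — streaming decode: 0.75-s windows every
  0.25 s, walk-posterior computation, 2-s posterior averaging, the
  idle/walk hysteresis state machine, and histogram-based threshold
  calibration.
- **`gaitbci.performance_metrics`** — lagged cue-vs-state cross-correlation,
  omission and false-alarm detection (attribution by episode onset), and
  per-subject/overall session aggregation.
- **`gaitbci.null_control`** — saturating AR(1) surrogate fitted to observed
  posteriors (alpha from the lag-1 autocorrelation, beta from mean
  matching), Monte-Carlo session simulation, and empirical p-values.
- **`gaitbci.synthetic_data`** — seed-deterministic cue-locked EEG (1/f
  background + calibrated narrowband walk modulation at a requested
  single-window log band-power d'), online sessions with a reaction delay,
  and gait-locked EMG/gyro traces.
- **`gaitbci.emg_validation`** — 40–400 Hz zero-phase EMG preprocessing,
  gyroscope step segmentation, per-step EMG power rank-sum comparisons
  across walking conditions, and state/EMG/movement onset-ordering checks.

## CLI

```sh
gaitbci simulate --kind training --seed 1 --effect-size 3 --format edf --out scratch/train
gaitbci simulate --kind online   --seed 1 --effect-size 3 --format edf --out scratch/online
gaitbci train  --eeg scratch/train.edf --cues scratch/train.cues.csv --out scratch/model.json
gaitbci decode --eeg scratch/online.edf --model scratch/model.json --ti 0.3 --tw 0.7 --out scratch/traces.csv
gaitbci evaluate  --traces scratch/traces.csv --cues scratch/online.cues.csv --out scratch/metrics.json
gaitbci null-test --posteriors scratch/traces.csv --cues scratch/online.cues.csv \
    --ti 0.3 --tw 0.7 --trials 10000 --seed 0 --out scratch/null.json
```

Delimited-matrix (`.tsv`) recordings carry channel names in the header row,
one column per channel and one row per sample; the sampling rate comes from
`--rate` or a sidecar config with a `rate_hz` key. Cue schedules are CSV
(`label,onset_s,duration_s`) or JSON.

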