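# infant-erp

A tested re-implementation of a two-group infant auditory/visual ERP
experiment pipeline: constrained stimulus scheduling, synthetic infant-EEG
cohort simulation, EEG preprocessing with gliding-window artifact
rejection, ROI/time-window ERP measurement, and mixed-design statistics.

Raw infant recordings for this design are not publicly available, so the
package ships a first-class simulator (`synthetic_eeg`) that generates
continuous 23-channel 10-20 recordings (250 Hz, Cz-referenced, bipolar
EOG, mastoids) with 1/f background noise, four injectable stimulus-locked
ERP components with configurable group/condition effect structure, and
blink/movement artifacts — enough to exercise and validate every stage of
the analysis end to end.

## Modules

- `infant_erp.study_design` — montage, ROIs, analysis windows
  (100–380 ms mean amplitude, 200–600 / 450–700 ms negative peaks,
  890–1000 ms mean amplitude), the constrained 200-trial schedule
  generator, stimulus geometry, and the packaged name-duration table.
- `infant_erp.synthetic_eeg` — background noise, Hann-bump component
  waveforms, per-subject continuous recordings, artifact injection,
  cohort generation.
- `infant_erp.preprocessing` — 0.3–20 Hz zero-phase 1501-tap FIR,
  linked-mastoid re-referencing, epoching (−200…+1500 ms), baseline
  correction, 200 ms gliding-window SD rejection (80 µV EOG / 50 µV
  elsewhere), ≥10-trials-per-condition inclusion rule.
- `infant_erp.erp_measurement` — condition averages, windowed mean
  amplitude, per-electrode negative-peak amplitude/latency, long-format
  measurement tables, grand averages.
- `infant_erp.stats` — mixed 2×2(×2) ANOVAs with partial eta squared,
  Scheffé/t post hocs, exact signed-rank tests, split-half and
  median-split (SNR) control analyses.
- `infant_erp.pipeline` / `infant_erp.cli` — staged, reproducible runs.

## CLI

```bash
infant-erp all --out run/ --seed 1 --n-subjects 15
# or stage by stage:
infant-erp simulate --out run/ --seed 1 --n-subjects 2
infant-erp preprocess --out run/
infant-erp measure --out run/
infant-erp stats --out run/
```

Each stage consumes only the previous stage's files under the run
directory (`raw/`, `epochs/`, `measures/`, `stats/`); `config.json`
records the full configuration, seeds, and library versions. A custom
configuration can be supplied as JSON via `--config`.

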