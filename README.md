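# fastkit

Tools for long continuous M/EEG recordings: memory-windowed data access,
BrainVision header-only import, EEG-fMRI artefact rejection (gradient and
pulse), sleep scoring structures and statistics, score-aware Welch
spectrograms, and slow-wave detection with scalp trajectory extraction.

## What's inside

| Module | Purpose |
| --- | --- |
| `fastkit.core` | `Recording` data model with a windowed-access contract (`read_window`), pure on-display transforms (`rereference`, `bandpass`), Welch PSD |
| `fastkit.io_formats` | BrainVision `.vhdr/.vmrk` header-only import (original binary linked in place), minimal EDF import, internal JSON+binary container |
| `fastkit.manipulate` | `append` (real-world-clock ordering, zero-filled gaps), `chunk` (by markers / time / clock), multi-file alignment |
| `fastkit.gradient` | Gradient-artefact rejection by averaged artefact subtraction (AAS): trigger-based or auto-detected scanning episodes, moving 30-epoch templates, anti-aliased downsampling to 500 Hz |
| `fastkit.pulse` | QRS detection (Teager energy, polarity invariant), pulse-artefact correction by Gaussian-mean, OBS-PCA, or the combined ≤4 Hz / ≥4 Hz split method |
| `fastkit.scoring` | Multi-scorer sleep stages (0 wake … 6 movement), hypnogram, FPL/OPL-bounded sleep statistics, tabular score import/export |
| `fastkit.spectral` | Whole-recording spectrogram with movement/artefact exclusion; absolute / relative / deep-sleep-normalized band power; per-stage mean spectra |
| `fastkit.slow_waves` | Five-criteria slow-wave detector on four ROI-averaged signals; per-electrode negative-peak delay maps |
| `fastkit.synth` | Synthetic generators with ground truth: 1/f background, TR-periodic gradient artefact, ECG + beat-locked pulse artefact, parameterized slow waves |
| `fastkit.cli` | `fastkit` command-line entry point |

## CLI

```sh
fastkit synth --preset ga -o raw            # synthetic EEG-fMRI fixture + truth JSON
fastkit ga raw.json --tr 2.0 --trigger-label fmri_volume_trigger -o clean
fastkit pa clean.json --method combined --ecg ECG --qc qc.json -o corrected
fastkit chunk corrected.json --t0 10 --t1 70 -o part
fastkit append a.json b.json -o joined
fastkit spectrogram corrected.json --channels Fz,Pz -o sg
fastkit score-stats scored.json --scorer alice
fastkit sw corrected.json --stages 3,4 --scorer alice -o waves.tsv
```

Recordings are stored as a `<name>.json` header plus `<name>.bin` float32
multiplexed binary; header edits never rewrite the binary. Lab defaults
(channel scales, bipolar pairs, ROI electrode lists, method defaults) live
in a YAML file passed via `--config` or `$FASTKIT_CONFIG`.

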