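# gutsound

Bowel-sound analysis pipeline for acoustic IBS classification: simulate
multi-channel abdominal recordings with ground truth, detect and segment
bowel sounds, extract time/frequency feature families, compute a logistic
**IBS Acoustic Index** (values ≥ 0.5 predict IBS), and evaluate it with
LOOCV, a k-fold battery, out-of-bag bootstrap and full diagnostic-accuracy
metrics, plus fed/fasted group statistics via a random-intercept linear
mixed model.

## Modules

| module | purpose |
| --- | --- |
| `gutsound.simulate` | synthetic cohorts: burst-train bowel sounds (damped sinusoids), Poisson-like event timing with optional MMC-style cyclic modulation, cross-channel leakage, artifacts, ground-truth tables |
| `gutsound.detection` | zero-phase band-pass, robust envelope thresholding, burst segmentation, origin-quadrant assignment, detection scoring |
| `gutsound.features` | per-sound time/frequency features, subband energy ratios, quantity density, scaled summed amplitude, per-participant aggregation, the 26-feature (8 time + 18 frequency) final-model registry |
| `gutsound.model` | L2-penalized logistic regression (damped IRLS), the IBS Acoustic Index, greedy forward feature selection with a plateau rule |
| `gutsound.evaluation` | 2×2 tables, sensitivity/specificity/PPV/NPV/LRs with Wilson / log-method CIs, LOOCV, 7-scheme k-fold battery, 300-rep bootstrap, exact Fisher test |
| `gutsound.group_stats` | random-intercept linear mixed model (profiled ML) with Wald χ² tests |
| `gutsound.io`, `gutsound.pipeline`, `gutsound.cli` | WAV/CSV/YAML I/O and the end-to-end pipeline |

## CLI

```bash
gutsound init-config config.yaml          # write a default config
gutsound pipeline --config config.yaml    # simulate -> ... -> stats
gutsound simulate --config config.yaml --out cohort/
gutsound detect --config config.yaml cohort/IBS001_fasted.wav --out events.csv
gutsound train --features run/features.csv --out model.yaml
gutsound predict --model model.yaml --features run/features.csv
gutsound evaluate --features run/features.csv --mode loocv
gutsound stats --features run/features.csv
gutsound report --out run/
```

`pipeline` writes a manifest, event table, feature matrix, model file,
evaluation report and mixed-model statistics under the configured output
directory, together with a run manifest recording the config hash and
master seed; reruns with the same config reproduce identical CSVs.

## Notes

- Recordings are 4 channels mapped to abdominal quadrants
  (RUQ/LUQ/RLQ/LLQ), PCM-16 WAV, 44.1 kHz by default; tests use scaled-down
  durations and sample rates.
- All randomness flows from a master seed; per-participant streams derive
  from a stable hash of `(seed, participant_id)`.
- The default final-model registry is a documented selection constrained
  to the named feature families and the 8 + 18 = 26 split, switchable by
  configuration.
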