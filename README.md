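# apneafusion

Explainable sleep-apnea event detection from paired ECG and SpO2 signals:

- **Synthetic data** — a paired ECG/SpO2 generator with programmed apnea
  events (RR-interval shortening in the ECG, lagged >= 4% desaturations in
  the SpO2 trace), both annotation dialects (event intervals and per-minute
  labels), class imbalance, and injectable motion-artifact bursts.
- **Ingest** — 11 s windows with 10 s overlap, per-window binary labels
  from either dialect, plain-text record I/O (WFDB reading optional).
- **Quality** — 1–40 Hz zero-phase Butterworth bandpass and
  autocorrelation-graph artifact rejection: per-window ACFs (via the power
  spectral density), pairwise cosine-similarity degree weights, and
  retention of the top 95% of windows by weight.
- **Models** — two fixed 1D-CNN branches (ECG: 3x100/s2, 50x10, 30x30;
  SpO2: 6x25, 50x10, 30x15; each conv followed by 2/2 max-pooling, input
  batch norm, dropout 0.25, 2-unit softmax heads) on a small pure-NumPy
  network engine with exact analytic gradients; feature-level fusion that
  freezes both trunks, concatenates the flatten features (2040 + 330) and
  trains a fresh dense head with *selective dropout* on the
  higher-sampling-rate branch (rate `1 - Fs_low/Fs_high` or
  `1 - neurons_low/neurons_high`).
- **Training / evaluation** — record-level 8:1:1 splits, minority
  oversampling + time-reversal augmentation, Adam with early stopping, the
  full metric suite (accuracy / precision / recall / specificity / F1), and
  a −20 dB AWGN robustness protocol corrupting 20% (train/val) or 11.42%
  (test) of windows in one or both modalities.
- **Explainability** — 1D Grad-CAM: temporally averaged class-score
  gradients weight the last conv feature maps, ReLU, upsample, min-max
  normalize, and quantize into LOW / MODERATE / HIGH importance bands, with
  a localization score against known desaturation regions.

No deep-learning framework is required: the network engine
(`apneafusion.nn`) implements the needed layers and backprop in NumPy,
which also powers the Grad-CAM gradients.

## CLI

```sh
apneafusion run --out runs/demo --seed 1          # full pipeline
apneafusion simulate --out runs/demo --seed 1     # or stage by stage:
apneafusion ingest --out runs/demo
apneafusion preprocess --out runs/demo
apneafusion train --out runs/demo
apneafusion fuse --out runs/demo
apneafusion evaluate --out runs/demo
apneafusion explain --out runs/demo
apneafusion report --out runs/demo                # print metrics.json
```

All commands accept `--config config.yaml` (see `apneafusion.config.RunConfig`
for the schema; `save_config` writes a template) and `--seed`. Every stage
directory is stamped with the config hash and seed; identical config + seed
reproduces bit-identical artifacts.

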