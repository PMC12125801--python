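# msaunet

A toolkit for small-organ CT segmentation with multi-scale spatial attention
U-Nets, built for fully reproducible, CPU-only experimentation:

- **`msaunet.arch`** — segmentation networks: channel-squeeze/spatial-excitation
  (sSE) attention, multi-scale spatial attention (MSSA), multi-scale feature
  extraction and fusion (MSFEF), and the residual MSA block in two variants
  (V1: one kernel bank 3/5/7; V2: two parallel banks 3/5/7 and 5/7/9), embedded
  into a batch-norm U-Net with a configurable number of MSA stages.
- **`msaunet.nn`** — a small numpy-backed neural-network framework (reverse-mode
  autodiff, stride-1 convolution, pooling, bilinear upsampling, batch norm,
  Adam). No GPU or deep-learning framework required.
- **`msaunet.phantom`** — a seeded generator of CT-like slice/mask pairs: a
  small, irregular (Fourier-perturbed ellipse), low-contrast target among
  gray-level-similar neighbor blobs on a noisy Hounsfield-unit background,
  with 7:1:7 train/val/test splitting.
- **`msaunet.preprocess`** — HU conversion, window/level normalization, CLAHE,
  and paired geometric augmentation (rotation/shift/shear/zoom) that applies
  one transform identically to image and mask.
- **`msaunet.loss`** — soft Dice loss (literal single-epsilon form by default,
  symmetric-epsilon variant available).
- **`msaunet.metrics`** — DSC, JSC, PPV, SE, Hausdorff distance (boundary
  pixels, Euclidean, optional percentile), RVD and VOE, with per-case records
  and mean±SD aggregation.
- **`msaunet.stats`** — one-way ANOVA with Fisher-LSD post-hoc pairwise tests.
- **`msaunet.pipeline` / `msaunet.cli`** — training, evaluation, prediction and
  ablation grids, driven by YAML configs and a single seed.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks brute-force metric
equivalence, Dice-loss closed forms, architecture contracts across the full
V1/V2 × 1–4-MSA-block grid, a gradient audit, learnability on 200 phantoms
(held-out mean DSC ≥ 0.85), ANOVA calibration, determinism, and split
arithmetic. The full run takes a couple of minutes on one CPU.

## CLI

```bash
# generate a seeded synthetic dataset (paired 16-bit PNG + mask + JSON spec)
msau phantom --n 15 --out data/ --seed 1

# train (YAML config; see tests/test_cli.py for a minimal example)
msau train --config config.yaml --out runs/exp1

# evaluate a checkpoint -> per-case CSV + aggregate JSON
msau evaluate --checkpoint runs/exp1/checkpoint.npz --n 50 --out reports/exp1

# segment one slice
msau predict --checkpoint runs/exp1/checkpoint.npz --image data/case_0000_image.png --out mask.png

# ablation grid (versions x attention x MSA-block count) + ANOVA/LSD table
msau ablate --config config.yaml --out ablation/ --seed 1

# compare saved per-case reports with ANOVA + LSD
msau compare --report-csv a_cases.csv --report-csv b_cases.csv --out cmp.csv
```

A config file can set any of the blocks `model`, `loss`, `preprocess`
(`window`, `augmentation`), `train`, and `data`; unset keys fall back to
documented defaults (abdominal window 50/400 HU, Adam at 1e-3, Dice loss with
epsilon 1e-6, V1 defaults to 3 MSA blocks and V2 to 2).

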