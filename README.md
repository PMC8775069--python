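# eegsep

Interictal EEG two-class discrimination (ES vs. PNES) with a wavelet +
CNN pipeline, subject-wise leave-one-out cross-validation, and a
permutation-entropy (PE) probe of the network's feature maps.

The pipeline:

1. **synthetic** — a two-class synthetic resting-EEG cohort generator
   (19-channel 10-20 montage, 256 Hz, 2-s epochs). Per channel the
   background is band-limited (0.5–32 Hz) 1/f noise plus an alpha
   oscillation; class *ES* receives band-limited noise bursts in
   {F3, F4, C3, C4, P3, P4} with amplitude proportional to an effect size
   `delta`, which raises those channels' ordinal complexity. `delta = 0`
   makes both classes identical in law.
2. **preprocessing** — zero-phase 3rd-order Butterworth band-pass
   (0.5–32 Hz), integer decimation to 256 Hz, artifact-mask-aware
   segmentation into non-overlapping 2-s epochs.
3. **wavelet** — per channel, 5-level DB4 decomposition (Mallat cascade,
   symmetric extension) and per-sub-band reconstruction
   [d1, d2, d3, d4, d5, a5], assembling epoch tensors of shape
   `epochs x 19 x 512 x 6`. The six band signals sum back to the original
   epoch (perfect reconstruction).
4. **cnn** — a pure-NumPy CNN (Conv 1x6/16 + ReLU, MaxPool 1x2,
   Conv 1x3/32 + ReLU, MaxPool 1x2, Dense 32, Dropout 0.3, Dense 16,
   sigmoid; 625,329 parameters) trained with Adam on binary cross-entropy.
   Feature maps at input/Conv1/Conv2 are exposed for interpretability.
5. **evaluation** — subject-wise LOOCV, patient-based majority voting over
   epoch predictions, and the metric suite (accuracy, precision, recall,
   F-measure, Cohen's kappa, ROC/AUC) with PNES as the positive class.
6. **baselines** — 684 handcrafted per-epoch features (Min, Max, Energy,
   Mean, Std, Skewness per channel and sub-band) feeding MLP1/2/3, SVM-RBF,
   LDA and QDA comparison classifiers.
7. **pe** — permutation entropy of inputs and Conv1/Conv2 feature maps per
   channel, Wilcoxon rank-sum class-separability tests, and
   Friedman + Nemenyi comparison of classifier accuracy tables.

## CLI

```bash
eegsep synth --subjects 18 --epochs 214 --delta 1.0 --seed 7 --out cohort/
eegsep preprocess --in cohort/ES01.txt --out ES01_epochs.npz
eegsep wavelet --in ES01_epochs.npz --out ES01_tensor.npz
eegsep train-cnn --tensor ES01_tensor.npz --labels labels.csv --out model.npz
eegsep evaluate --cohort cohort/ --cnn-epochs 10 --out results/
eegsep baselines --cohort cohort/ --model MLP2 --out results_mlp2/
eegsep interpret-pe --cohort cohort/ --order 3 --delay 1 --out pe_results/
```

`eegsep synth --continuous` writes 20-minute records with random
2-s-aligned artifact masks for exercising the preprocessing stage;
`--fmt edf` writes EDF instead of the tab-separated text dialect.

A full-scale `evaluate` run (36 subjects x 214 epochs, 10 training passes,
36 folds) takes a few hours on one CPU; use `--max-epochs` and
`--cnn-epochs` to scale down.

## Conventions worth knowing

- Epoch-level labels: PNES -> 0, ES -> 1 (sigmoid output > 0.5 means ES).
- Subject-level metrics treat PNES as the positive class (TP = PNES
  correct).
- The CNN rescales inputs by the global training-set standard deviation by
  default (`normalize_input=False` disables it); microvolt-scale inputs
  otherwise saturate the sigmoid and stall a 10-pass training budget.
- PE uses order 3, delay 1, log base 2, with ties broken by order of
  appearance; values are bounded by log2(6) bits.
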