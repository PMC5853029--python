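# focusqc

Absolute microscope image focus-quality assessment for high-content
screening, built for image-analysis engineers and core-facility scientists
who need unattended per-image quality control.

Classical focus metrics such as the power log-log slope (PLLS) only rank
images relative to each other: deciding whether a single image is in focus
still needs a human-chosen, per-channel threshold.  `focusqc` instead
predicts an *absolute* defocus level — one of 11 ordered classes, level L
corresponding to a defocus of L × 2 μm from the focal plane — on each
84 × 84 patch of an image, together with a certainty for every call.

The core pieces:

- **Physics-based synthetic defocus** (`focusqc.optics`): the scalar
  diffraction PSF
  `h(x,y,z) = |C ∫₀¹ J₀(k·(NA/n)·r·ρ)·exp(−½jkρ²z(NA/n)²)·ρ dρ|²`
  (k = 2π/λ, defaults NA 0.5, n 1.0, λ 500 nm), plus Poisson sensor noise
  with camera gain and offset.  Convolving in-focus images with these
  kernels manufactures labeled training data — no manual annotation.
- **Ordinal patch classifier** (`focusqc.patches_model`): a small CNN
  (conv 32@5×5 → pool → conv 64@5×5 → pool → FC 1024 → dropout → FC 11 →
  softmax) trained with the ranked probability score
  RPS = Σᵢ (Pᵢ − Tᵢ)² over cumulative distributions, so errors are charged
  by ordinal distance.  Training patches get random log-uniform gain
  (0.2–5.0) and offset (1–1000) augmentation to make predictions
  brightness-invariant.  The network and its training loop run directly on
  NumPy/BLAS — no deep-learning framework required.
- **Certainty and aggregation** (`focusqc.certainty`):
  certainty = 1 − H(p)/log N maps uniform → 0 and one-hot → 1; whole-image
  predictions are certainty-weighted averages of patch distributions, so
  empty background patches don't dilute the call.
- **PLLS baseline and evaluation harness** (`focusqc.plls_baseline`,
  `focusqc.evaluation`): radially averaged power spectra, log-log slope
  fits, F-score threshold selection, 11-level confusion matrices, within-k
  accuracy and gain/offset robustness grids.
- **Synthetic scene generator** (`focusqc.fixtures`): seeded nuclei-like
  blob scenes, so the whole pipeline is testable offline.

## Worked example

```python
from focusqc import (OpticalParams, SceneSpec, SensorModel, ModelSpec,
                     TrainConfig, make_dataset, train)
from focusqc.evaluation import confusion, predict_levels, within_k_accuracy

params, sensor = OpticalParams(), SensorModel()
train_set, test_set = make_dataset(
    n_scenes=24, spec=SceneSpec(), params=params, sensor=sensor,
    patches_per_image=24, seed=7)

model = train(train_set, ModelSpec(),
              TrainConfig(steps=1500, batch_size=16, learning_rate=1e-3,
                          augment=True, seed=1))

fg = test_set.foreground_flags            # focus is defined on foreground
pred = predict_levels(model, test_set.patches[fg])
cm = confusion(test_set.labels[fg], pred)
print(f"exact accuracy      {within_k_accuracy(cm, 0):.3f}")
print(f"within-one accuracy {within_k_accuracy(cm, 1):.3f}")
```

Output from this exact run (about 17 minutes on one CPU):

```
exact accuracy      0.435
within-one accuracy 0.863
```

Read: after a 1,500-step desk-scale training run, the classifier pins the
exact defocus level (one of 11, spaced 2 μm apart) on ~43% of held-out
foreground patches and is within one level — roughly a 3-pixel difference
in blur diameter — on ~86%.  Accuracy is still rising at this step count:
the same configuration reaches ~0.90 within-one at 3,000 steps and ~0.93
at 4,500, so machines (or patience) that afford more steps get closer to
the published large-scale regime.

Per-patch predictions with certainty, whole-image aggregation and the
annotated-border visualizations are in `focusqc.certainty`; the PLLS
baseline in `focusqc.plls_baseline`; a CLI (`focusqc fixtures | simulate |
train | predict | plls | evaluate`) wraps all of it for shell use.

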