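# Methods

## The problem

Automated microscopes acquire image sets far too large to survey by eye,
and hardware autofocus leaves a fraction of frames out of focus.  Classical
focus metrics (variance ratios, spectral slopes) only *rank* images: turning
a ranking into an in/out-of-focus call needs a per-dataset, per-channel
threshold chosen by a human.  `focusqc` implements the alternative: learn an
*absolute* measure of defocus, defined as one of 11 ordered physical defocus
levels, predicted independently on small image patches with an attached
certainty, so that a single image can be assessed in isolation.

## Physics-based training data

Ground-truth defocus labels are manufactured, not annotated.  An in-focus
image is convolved with the scalar-diffraction point spread function of a
circular-aperture objective at defocus depth z,

    h(x, y, z) = | C ∫₀¹ J₀(k·(NA/n)·r·ρ) · exp(−½ j k ρ² z (NA/n)²) · ρ dρ |²,

with wavenumber k = 2π/λ, and level L assigned to z = L·Δz.  Defaults:
NA = 0.5, n = 1.0, λ = 500 nm, Δz = 2 μm, 11 levels (z = 0…20 μm).  The
kernel is evaluated per pixel by composite Simpson quadrature with 201
nodes over ρ ∈ [0, 1] (doubling the nodes changes no weight by more than
1e-6), squared, and normalized to unit sum.  At z = 0 the integral has the
closed Airy form (2·J₁(v)/v)², which the test suite uses as an independent
reference; the kernel is even in z because only the modulus of the
conjugate-symmetric integrand survives.

The camera pixel size is not a physical constant of the model but sets the
kernel's discretization; the default 0.65 μm/pixel corresponds to a 6.5 μm
sensor pixel at 20× magnification with 2× binning and yields 80%-energy
blur diameters growing approximately linearly from ~3 px (level 1) to
~26 px (level 10), i.e. the intended "a few to tens of pixels" regime.
Kernel support defaults to 1.5× the geometric blur radius z·NA/n plus a
4-pixel margin; a warning is raised if more than 10% of the kernel mass is
truncated.  Convolution uses reflective padding so image borders do not
acquire a spurious dark halo that would mimic defocus.

Sensor noise is applied after blurring: expected photoelectrons
e = max(image − offset, 0)/gain, a Poisson draw per pixel, then mapped back
through gain and offset and clipped to [0, 65535].  The order
(subtract offset → Poisson → reapply) is a modeling choice; offset 100
counts and gain 2 counts/e⁻ are defaults in the plausible range of sCMOS /
CCD plate readers.  Level 0 of a stack is the noised original.

## Synthetic scenes

The bundled generator renders sparse nucleus-like blobs — sharp-edged
disks (radius 5–9 px, smoothstep edge of 0.7 px) carrying 3–7 bright
internal Gaussian speckles (σ 0.8–1.5 px), peaks 3,000–30,000 counts,
25–45 blobs per 696 × 520 16-bit frame on a constant 100-count
background — emulating Hoechst-stained nuclei in plate-based screens.

The sharp envelope and pixel-scale speckles are load-bearing, not
cosmetic.  A smooth Gaussian blob of unknown width and brightness is
nearly degenerate under defocus: blurring a narrow blob reproduces a
wider in-focus one, so the defocus depth of such a scene is not
identifiable by *any* method at low z.  Real nuclei escape this because
their envelope edge and chromatin texture are sharp at the camera's
resolution — exactly the features defocus destroys first — and the
generator reproduces that property.  What it does not reproduce is
realistic chromatin structure, nucleus shape variation, clumping, uneven
illumination or debris; passing tests on these scenes validate the
pipeline's mechanics and the physics of the defocus model, not
performance on real screens.

Datasets split scenes 50/50 into train/test *before* patch extraction
(scene ≈ imaging site), so no pixel leaks across the split.  Each stack
member contributes randomly positioned 84 × 84 crops labeled with the
stack level; a patch is flagged foreground when it intersects any blob's
2σ support.  Background-only patches carry no focus information — they are
kept in training (the model must learn to be uncertain on them) and
excluded from foreground accuracy metrics.

## The ordinal classifier

Architecture: conv 32 @ 5×5 → 2×2 max-pool → conv 64 @ 5×5 → 2×2 max-pool
→ FC 1024 → dropout 0.5 → FC 11 → softmax, valid (unpadded) convolutions,
ReLU activations, truncated-normal initialization with a fixed seed.
Input patches are fed as raw counts scaled by 1/65535.  Per-patch
standardization would be the conventional choice but is deliberately
avoided: it would erase exactly the gain/offset variation that the
photometric augmentation (below) is designed to teach the model to ignore,
and would make the robustness evaluation vacuous.

The loss is the discrete ranked probability score,
RPS = Σᵢ (Pᵢ − Tᵢ)² over cumulative distributions, which charges an error
by its ordinal distance (a one-hot prediction d levels away costs exactly
d), unlike cross-entropy which charges all wrong levels equally.

Each training patch is augmented with a random gain, log-uniform in
(0.2, 5.0), and a random offset, log-uniform in (1, 1000) counts, applied
as clip(x·g + o, 0, 65535) before input scaling.  The geometric mean of
the gain distribution is exactly 1.

The network layers, backward passes and the Adam optimizer are implemented
directly on NumPy: convolutions lower to BLAS matrix products (im2col on
the forward pass and weight gradients; shifted tensordot accumulation for
input gradients), max-pool backward routes gradients to the first maximum
in each window, and Adam updates run in-place against preallocated scratch
buffers because the FC-1024 layer's ~21 M parameters dominate memory
traffic.  Gradient correctness is pinned by a central-difference check on
a reduced network in the test suite.

### Desk-scale training regime

Defaults are sized for a single CPU worker: batch 16, a few thousand Adam
steps, learning rate 1e-3 with a 50-step linear warmup and cosine decay
to 0.2× the peak, and global-norm gradient clipping at 5.  The
large-scale regime this replaces (64 replicas, 10⁶ steps, learning rate
5e-6) is preserved as `paper_scale_config()`; at desk scale that learning
rate moves the parameters by ~10⁻² in total and cannot converge, so the
desk default is retuned to the step budget.

Two further training-loop choices matter at this scale:

- *Foreground-weighted sampling.*  Background-only patches carry no focus
  signal; their optimal prediction (near-uniform) is learned almost
  immediately.  Minibatches therefore sample foreground patches with 3×
  the weight of background ones, concentrating gradient signal where
  focus is defined while keeping background patches in the mix.
- *Dihedral augmentation.*  Fluorescence micrographs are rotation and
  reflection invariant, so each training patch is presented in a random
  one of the 8 flip/rotation orientations — free diversity that directly
  attacks the train/test gap of a 12-scene training set.

The reference experiment used throughout the end-to-end checks is: 24
scenes (generator seed 7), 24 patches per stack image (3,168 training
patches), batch 16, up to 20,000 steps under a wall-clock budget.  The
budget (15 minutes for the reproduction script) stops training at
whatever step count the host machine affords, with the cosine decay
horizon calibrated from the first few steps, so faster machines train the
same experiment further along the same curve.  On a single desk CPU this
is roughly 1,500–2,000 steps — deep into diminishing returns for clean
test accuracy, but (see limitations) not enough to fully master the rare
large-offset corner of the photometric augmentation distribution.

## Certainty and aggregation

certainty(p) = 1 − H(p)/log N with H the Shannon entropy (0·log 0 = 0):
0 for uniform, 1 for one-hot, invariant to permuting levels — it measures
peakedness only.  The whole-image distribution is the certainty-weighted
average of patch distributions; background patches, being near-uniform,
carry almost no weight.  The aggregate certainty is defined as the
*normalized* certainty of that average (not its raw entropy) so that the
mean-vs-aggregate scatter lives on a shared [0, 1] × [0, 1] scale; if
every patch has exactly zero certainty the aggregate falls back to the
unweighted mean with a warning (the weighted form is 0/0).

Visualization conventions: 11 evenly spaced hues with level 0 anchored at
red, border lightness linear in certainty (certainty 0 renders black);
patch borders are drawn on the patch's own perimeter pixels; the montage
bins certainty into 10 right-closed bins (certainty 1.0 falls in the top
bin) and shows the first sample per (level, bin) cell.

## PLLS baseline

The power log-log slope is the OLS slope of log(radially averaged
periodogram) against log(spatial frequency).  Estimator choices (the
original implementations leave them open): mean subtraction before the
FFT (hence offset invariance; gain invariance is automatic for a slope in
log space), equal-width radial bins over (0, 0.5] cycles/pixel with
width min(side)/4 capped by the bin count, fit band 0.05–0.45
cycles/pixel, no window by default (optional Hann).  The patch framework
applies PLLS to each 84 × 84 tile and averages the finite slopes —
certainty weighting is undefined for a scalar metric, so the plain mean is
used.

## Evaluation protocols

*Binary*: scores are reduced from the 11-class aggregate by expected level
Σ i·pᵢ (argmax and 1 − p₀ are selectable); a threshold maximizing F-score
is picked on a random 10% validation split from midpoint candidates
(sentinels beyond the extremes included, ties to the lowest threshold) and
applied to the remaining 90%.  On synthetic stacks the binary ground truth
calls levels {0, 1} in-focus and {2–10} out-of-focus (configurable) — with
2 μm steps and ~3 px of blur per level this mirrors a "one level of slack"
notion of acceptably focused.

*Absolute*: raw-count confusion matrices over all 11 levels, summarized by
within-k accuracy (fraction within |pred − true| ≤ k; non-decreasing in
k), optionally across a gain × offset grid of photometrically perturbed
test patches with the identity cell (gain 1, offset 0) as reference.

### How far PLLS can order defocus

On the synthetic stacks, whole-image PLLS falls strictly over the first
two or three defocus levels and then stops ordering.  Two mechanisms,
both verified experimentally, cap it.  First, the Poisson shot-noise
floor is white: once blur removes the signal from the fit band, the
measured slope relaxes toward the floor's flat spectrum (subtracting an
estimated floor removes this relaxation but not the second effect).
Second, once the defocus OTF's first zero drops below the fit band, the
band-averaged log-log slope of the blurred spectrum becomes essentially
scale-invariant — the disk-OTF envelope contributes a fixed power law —
so adjacent high defocus levels are spectrally indistinguishable by
slope.  The effect is robust to the fit band, Hann windowing,
noise-floor subtraction and scene density.  This is the quantitative
face of PLLS's known character: a good *relative* ranking near focus and
a useful binary separator, not an absolute depth estimator — precisely
the gap the patch classifier fills.

## Numerical and degenerate-input conventions

Probability vectors are validated to 1e-5; kernel normalization to 1e-9.
Constant images: the PSD is flagged and PLLS raises (slope of an all-zero
spectrum is undefined).  Best-focus selection breaks ties toward the
lowest stack index.  Thresholds at ties resolve to the smallest candidate.
All stochastic operations are pure functions of their inputs and a seed;
16-bit clipping is applied at every photometric step.

## Known limitations

- The scalar, radially symmetric PSF ignores spherical aberration,
  vectorial high-NA effects and depth-variant blur.
- Synthetic disk-and-speckle scenes under-represent real nuclear texture
  and morphology, so desk-scale accuracies here do not transfer to real
  screens without retraining or validation on real stacks.
- The NumPy training loop is single-threaded and desk-scale by design;
  reproducing the published large-scale regime would need a GPU framework
  and days of compute.  Two consequences of the desk-scale step budget
  are visible in the end-to-end checks: patch-level within-one accuracy
  converges into the high 80s rather than the mid 90s (and the accuracy
  curve is still rising when the budget ends), and photometric-robustness
  of the augmented model is incomplete for the largest offsets, which the
  log-uniform augmentation presents only rarely (about 10% of draws
  exceed offset 500).  Both quantities improve monotonically with steps.
- Patch-level accuracy is a strictly harder statistic than whole-image
  accuracy: a whole-image call averages ~48 patch distributions weighted
  by certainty, which suppresses exactly the partial-nucleus patch errors
  that dominate the patch-level confusion matrix.
- The binary protocol on synthetic data uses level-derived ground truth,
  not human ratings, so its F-scores are not comparable to published
  values on human-labeled collections.
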