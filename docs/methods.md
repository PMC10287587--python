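# Methods

This note documents the models and procedures `slseg` implements, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer should know about.

## The segmentation problem and the ensemble model

The target is binary segmentation of lipomatous tumors in 3D MR volumes
processed slice-wise by 2D networks. Multicenter data violate the usual
i.i.d. assumption in a specific way: the *intensity scale* is
site-dependent (offset, gain, effective gamma) and each exam carries a
smooth multiplicative bias field. No single intensity normalization is
uniformly best, so the pipeline trains one network per
preprocessing-variant and stacks them.

Given m base learners with per-voxel tumor probabilities p_ji (learner j,
voxel i), the Super Learner prediction is the convex combination
p_SL,i = Σ_j w_j p_ji. The weights live on the probability simplex and are
fit on a held-out tuning split by minimizing the summed cross-entropy of
the combined probability against the reference labels. Modeling
assumptions worth stating:

- the combination is linear and global (one weight per learner, no spatial
  or per-exam dependence);
- the tuning split is assumed exchangeable with the test split — weights
  generalize only as far as that holds;
- cross-entropy, not dice, is the stacking loss: it is strictly proper, so
  with calibrated learners the optimum rewards probabilistic accuracy per
  voxel, and it is convex in w given fixed p.

Because the loss is convex on the simplex, the fitted weights can never be
worse (on the tuning data) than the best vertex — i.e. the best single base
learner — up to optimization tolerance. The test suite asserts exactly this
dominance property, plus recovery (weight ≥ 0.99) of a planted
perfect learner.

### Weight-fit mechanics

Feasibility is enforced by parameterizing w = softmax(z) with logits z
initialized to zero, so the start is the uniform 1/m vector and every
iterate is exactly feasible. Optimization is full-batch Adam (lr 0.05,
default budget 200 epochs) with early stop once the loss improves by less
than 1e-8 per voxel for 10 consecutive epochs. The combined probability is
clipped to [1e-7, 1 − 1e-7] before logs; clipped voxels get zero gradient.
Single-class (degenerate) truth leaves the weights uniform with a warning.
A final exact renormalization guarantees Σw = 1 to machine precision. If
the loss somehow ends above its starting value the fit falls back to
uniform weights rather than returning something worse than no stacking.

## Base learners

**Architecture.** Standard encoder–decoder U-Net: `levels` double-conv
blocks (3×3 convolutions, batch norm, ReLU), 2×2 max-pooling, feature
counts doubling from `root_features`; decoder with 2×2 stride-2 transposed
convolutions, skip concatenation, double convs, and a final 1×1
convolution + sigmoid. The attention variant gates each skip with additive
attention: 1×1 projections of the skip and the coarser gating signal
(projection width = skip width), bilinear 2× upsampling of the projected
gate, ReLU, 1×1 to one channel, sigmoid, multiplied onto the skip. Inputs
must be divisible by 2^(levels−1).

The engine is pure numpy (im2col convolutions as batched matrix products,
explicit backward passes, exact adjoints for every operator including the
bilinear upsampler). Backprop was verified against central differences in
float64 to relative error ~5e-10; at practical float32 precision the
network is deterministic given its seed. Batch norm uses running statistics
at inference (momentum 0.9, eps 1e-5); weights are He-initialized.

Two named configurations: the desk-scale network (levels 3, root 4,
~29k parameters) used throughout the tests, and the publication-scale one
(levels 5, root 32) which is constructible and counted but not trained in
CI. `count_parameters` is an analytic count validated against enumeration
of the instantiated parameter arrays and against a hand count (26) for the
minimal one-level, one-feature configuration.

**Loss.** Dice loss over the batch: 1 − (2Σpy + ε)/(Σp + Σy + ε) with
ε = 1e-6. The ε keeps all-empty batches finite, so slices without tumor
stay in the training pool. Optimizer: Adam, lr 1e-3, no schedule; batch
size 16 slices.

**Augmentation.** Per slice: horizontal/vertical flips (p = 0.5 each), one
rotation in ±15°, one isotropic zoom in [0.9, 1.1] about the slice center,
resampled back onto the input grid (bilinear image, nearest-neighbor mask,
so masks stay binary). Rotation and zoom are composed into a single affine
resample; the fill value is the slice minimum.

**Cross-validation.** A single 80/9/11 train/tune/test split
(largest-remainder rounding, so 185 exams give exactly 148/17/20), then
seeded K-fold assignment of the training exams with fold sizes differing by
at most one. Each variant trains once per fold (fold = validation); Nyul
standard scales are learned from that fold's training exams only, on the
same intensities (bias-corrected or raw) the normalization will see.
Fold assignment is unstratified; tumor-location balance across folds is not
enforced.

## Preprocessing

**Bias correction** is an N4-style estimator built for this package: work
in the log domain; sharpen the intensity histogram onto its detected modes
(128 bins, Gaussian-smoothed by 1.5 bins, peaks above 0.5% prominence, each
voxel assigned its class's mean log-intensity); fit a smooth field to the
residual by per-cell medians on a coarse control grid upsampled with cubic
B-splines; iterate the sharpen/fit cycle (max 50 iterations, tolerance
1e-4 in log units, typically < 10). The control-cell extent defaults to
1/3 of the in-plane field of view — coarse enough that anatomy cannot be
absorbed into the field. The fitted field has zero log-mean, so global
scale is preserved; constant volumes pass through unchanged. The cell
medians make the fit robust to compact structures (the tumor) that the
histogram step occasionally misassigns. An earlier adapter around a
general-purpose N4 implementation was dropped after it systematically fit
anatomy on these small few-class volumes.

**Normalizations.** Z-score and min–max are computed over the whole 3D
volume (per-slice min–max being the explicitly slice-wise variant);
constant inputs return zeros with a logged warning instead of raising, so
batch pipelines survive blank padded slices. Nyul standardization learns
landmark intensities at percentiles {1, 10, 20, …, 90, 99} of the
foreground histogram (foreground = voxels above the mean of the nonzero
voxels), affinely anchors each training volume's low/high landmarks to the
standard range (0, 100), and averages; application is the monotone
piecewise-linear map through the volume's own landmarks with linear
end-segment extrapolation. Intensities below the low anchor can therefore
map to negative standard values — intentional, as clamping would destroy
ordering.

**Resampling.** Slices are scaled isotropically so the larger in-plane
dimension hits the target (bilinear image, nearest mask), the remainder is
zero-padded symmetrically, and in-plane spacing is divided by the scale
factor. The slice axis is never resampled (the networks are 2D).

## Evaluation metrics

DSC = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), all validated against a per-voxel brute-force
counter. Two empty masks define DSC = 1 (with a warning); sensitivity and
specificity are NaN when their denominators vanish.

HD95 pools the *bidirectional* nearest-neighbor distances between boundary
voxel sets (boundary = mask voxel with a face-adjacent background neighbor,
grid edges counting as background) and takes the 95th percentile with
linear interpolation, in mm under anisotropic spacing. Pooling makes the
statistic symmetric; some tools instead take the max of two directed
percentiles, which differs — the all-pairs brute-force oracle in the tests
pins this package's convention. The result is undefined (None, not an
exception) if either mask is empty. Computation is volumetric 3D by
default with a per-slice 2D option.

The voxelwise ROC AUC is the normalized rank-sum statistic (tie-aware,
identical to trapezoid integration over the tie-grouped curve); constant
maps give 0.5 and single-class references are flagged undefined. Per-exam
reports aggregate into per-location and overall means with improvement
rows: signed difference for the [0,1]-bounded metrics, percent reduction
for HD95 (11.5 mm → 1.7 mm reads as 85.2%). Undefined HD95 entries are
excluded from means, with the contributing count reported.

## Synthetic cohort

Each phantom is built as anatomy × bias × site-style + noise, fully
determined by (seed, exam index):

- anatomy: muscle background (0.35), a sharp-edged subcutaneous-fat band
  (1.0), and a tumor of 1–3 overlapping random ellipsoids whose intensity
  is fat × a contrast factor; sharp class boundaries keep the bias/anatomy
  decomposition identifiable, which mirrors real fascia boundaries;
- bias: exponentiated low-pass-filtered Gaussian noise, unit mean,
  amplitude 0.3 (peak log-deviation), in-plane correlation length 16
  voxels;
- site styles: three (offset, gain, gamma) triples spanning a ~500×
  intensity-range spread, cycled round-robin, emulating scanner/protocol
  conventions;
- noise: additive Gaussian, sd 3% of the site gain.

Defaults: 60 exams of 8×64×64 voxels at (5, 1, 1) mm spacing, tumor
in-plane radii 7–14 voxels, contrast 1.4–1.9 relative to fat. These sizes
were chosen so the complete 6-variant × 5-fold study (30 base learners,
8 epochs each) runs end-to-end on a single CPU in roughly ten minutes;
they are the configuration every end-to-end number in this repository
refers to. The homogeneous regime (`easy_config`: no bias, no noise, one
site) makes tumors exactly threshold-separable and provides a perfect-DSC
oracle for end-to-end tests.

What the phantoms do **not** emulate: partial-volume effects, texture
within tissues, anatomy more complex than band-plus-ellipsoids, k-space /
relaxometry physics, fat-saturation or multi-sequence acquisitions, and
tumors isointense to their surroundings. Passing the suite therefore
demonstrates that the machinery (preprocessing, training, stacking,
metrics) is correct and that stacking beats single learners under
controlled heterogeneity — not that the trained weights transfer to
clinical images.

## Numerical decisions and edge cases

- Thresholding uses ≥, so a uniform 0.5 map is all-tumor rather than
  silently empty.
- Probability clipping at 1e-7 bounds the SL loss; dice ε = 1e-6.
- Split/fold/init/augmentation/fit seeds all derive from one global seed
  via independent seed-sequence spawns, so any stage can be reproduced in
  isolation.
- Largest-remainder apportionment breaks ties by group order.
- Bias-corrected volumes are cached per exam and shared across the five
  variants and folds that need them.
- Test-split exam ids never enter training pools or the weight fit;
  the orchestrator asserts this by id bookkeeping.

## Known limitations

- The numpy engine is single-threaded and CPU-bound; publication-scale
  training (levels 5, root 32, 512×512, 120 epochs) is out of its intended
  range.
- One global weight vector per run: no per-location or per-voxel stacking,
  no nonlinear meta-learner.
- 2D slice-wise networks only; no 3D context.
- The bias-correction estimator assumes a few-mode intensity histogram;
  on images with continuous intensity gradients inside a tissue class it
  will under-correct (by design, to avoid absorbing anatomy).
- DICOM support covers plain image series (one series per exam, mask as a
  parallel series); no RT-STRUCT, no anonymization.
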