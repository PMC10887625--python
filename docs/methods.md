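# Methods

## Problem and approach

Multispectral food analysis images a dish once under white light (an RGB
image) and once per narrow-band LED wavelength in the near-ultraviolet and
near-infrared (385–1020 nm). Stacking the band images with the RGB planes
improves food classification and caloric estimation, because foods that are
metameric under visible light — coffee with and without dissolved sugar —
can differ strongly in UV/NIR reflectance. Acquiring every band is costly
(one light source and one exposure per wavelength), so the central question
is whether band images *predicted from the RGB image alone* can stand in for
actual narrow-band captures.

`specfood` implements that pipeline end to end on synthetic scenes:

1. `spectral_scene` — a scene generator with planted spectral structure;
2. `conversion` — an encoder–decoder CNN mapping RGB → one band image;
3. `analysis_cnn` — a small CNN over stacked 64×64 planes with a softmax
   (classification) or linear (caloric regression) head;
4. `wavelength_selection` — stepwise add/remove search over band subsets;
5. `metrics_report` — PSNR, SSIM, MAPE, accuracy and the secondary
   statistics (correlations, sample standard deviations, relative
   reductions, per-selection quality averages) plus table/report rendering;
6. `dataset_io` — 16-bit TIFF/CSV persistence, the 10:1 train/validation
   split, and the 5 kcal floor for zero-calorie items;
7. `cli` — a config-driven command-line front end.

## The synthetic scene model

Each food class is a piecewise-linear reflectance spectrum over
385–1020 nm with knots on a fixed grid, values in [0, 1]. A scene is one
elliptical food blob (centre jitter, radius 0.20–0.30 of the image side,
eccentricity ≤ 0.5, pose-dependent rotation) on a uniform tray of
reflectance 0.15 at every band. Food pixels at band λ take the value
`spectrum(λ) · shading`, where shading is a radial cosine falloff from a
pose-shifted illumination centre (range ≈ 0.7–1.0); the RGB channels
integrate the spectrum against three Gaussian sensor responses centred at
460/540/620 nm (σ = 35 nm), truncated to < 700 nm and normalised to unit
mass. Additive Gaussian pixel noise (default sd 0.02, clipped to [0, 1])
models sensor noise. Images are floats in [0, 1]; the 16-bit sensor depth
exists only at file I/O, which keeps the PSNR peak term at 1.0.

**Confusable pairs.** A pair shares its spectrum exactly below 700 nm and
differs by exactly the planted contrast δ (default 0.3) at the planted
bands (default 850 and 970 nm). Because the RGB responses have no support
at or above 700 nm, noiseless RGB renders of pair members with matched
pose and seed are pixel-identical.

**Calories.** Each record's kcal is `kcal_density × (food-pixel count /
reference area)` with the reference area 20 % of the frame, so caloric
estimation requires both identity (density) and portion size (area). The
5 kcal floor replaces exact zeros before regression training and MAPE
evaluation, since a relative error is undefined at zero truth.

What the generator does *not* model: food texture, specularity, shadows,
LED spectral bandwidth, camera quantum-efficiency curves, the IR-cut
filter, or photorealistic shape. Passing tests therefore demonstrate the
pipeline's statistical behaviour under the planted structure, not
performance on real photographs.

## Conversion network

A U-net-style encoder–decoder: 3×3 same-padded convolutions, ReLU, 2×2
max pooling on the way down, nearest-neighbour 2× upsampling with
concatenated skip connections on the way up, and a sigmoid output so
predictions stay in [0, 1]. The full-size channel profile is
3-16-32-64-128-256-256-128-64-32-16-1 (four poolings; inputs must be
divisible by 16). Training minimises the mean squared error between
predicted and actual band images by plain mini-batch SGD
(`W ← W − λ·∇E`); classical momentum is available behind `TrainConfig`
but off by default. One model is trained per target wavelength and then
frozen; selection never retrains converters. Reported loss is per-pixel
MSE averaged over the epoch's mini-batches, so a learning rate of zero
yields an exactly constant history.

Synthetic experiments use a two-pool profile (3-8-16-32-32-16-8-1) and
64×64 or 32×32 scenes; on a single CPU core this trains in tens of
seconds where the full profile would take hours at camera resolution.
The networks are implemented on a small NumPy layer engine (`_nn`):
im2col + BLAS matrix products for both passes, with every analytic
gradient checked against central finite differences in the test suite.

## Analysis network

Input is a stack of 64×64 planes: 3 RGB planes plus one plane per
selected wavelength. Larger frames are reduced to 64×64 by bilinear
interpolation with antialiasing — the whole frame, no cropping, so
background/portion cues survive. The trunk is three conv(3×3)+ReLU+pool
stages with 16-32-64 channels and a dense ReLU layer of 128 units;
the head is either a softmax over classes trained with cross-entropy or
a single linear output trained directly with MAPE (differentiable almost
everywhere; a 1e-6 guard on the denominator). Mini-batch size defaults
to 32. Inputs are centred by −0.5 before the first convolution; without
centring, all-positive planes make plain SGD collapse to the uniform
softmax at practical learning rates. Defaults are lr 0.01 with momentum
0.9; regression targets are divided by their mean during training (MAPE
is scale-invariant, so the optimum is unchanged) and rescaled at
prediction, which keeps the head's gradient scale unit-free. The
regression head bias starts at the (normalised) target mean.

## Wavelength selection

Sequential forward floating selection: add the single candidate with the
best validation score (ties break toward the smaller wavelength), then
repeatedly drop any band whose removal *strictly* improves on the best
set already known at the smaller cardinality. The search continues to
`max_size` even through non-improving additions so every cardinality is
recorded; an exact score tie on the forward step stops the search. RGB
is an implicit member of every set and is never removed. Every evaluated
subset is cached and the best evaluated set per cardinality is reported,
mirroring the experiment tables.

Stepwise selection is a heuristic: for additive (interaction-free)
subset scores its per-cardinality optima provably coincide with
exhaustive enumeration — the oracle-equivalence test class — but for
arbitrary interacting scores it can miss optima (that approximation is
the reason to prefer it over a 2^N grid). The floating backward step
recovers a classic synergy case (two bands jointly dominant, neither
best alone), which the unit tests pin.

## Reference statistics

`specfood.reference` bundles the published per-wavelength conversion
quality and selection-path tables from the original 101-food study the
package models, as printed (the underlying camera dataset is available
only on request). `metrics_report` recomputes the study's secondary
statistics from them: sample standard deviations use the n−1 convention
(this reproduces the printed 1.38 for PSNR; the n convention gives
1.31); the accuracy-vs-PSNR correlation over the predicted-image
selection rows reproduces 0.340 exactly; the accuracy-vs-SSIM value
computes to −0.5212 against a printed −0.522, and the SSIM standard
deviation to 0.0414 against a printed 0.042 — final-digit artifacts of
the printed tables. Correlations the printed tables do not support
(accuracy vs wavelength count 0.767; the −0.8471/1.034 regression for
actual-image estimation; MAPE vs PSNR/SSIM −0.097/−0.256) are computed
and reported but not asserted.

## Standing experiments

`experiments.conversion_recovery` — 4 classes whose 850 nm reflectance
is an exact linear combination (weights summing to 1) of the RGB channel
values, 80 noiseless 32×32 scenes; converter trained with lr 0.3 and
momentum 0.9 for 100 epochs (plain SGD at the learning rates this loss
tolerates converges too slowly and is marginally stable across
initialisations, so the standing experiments enable the momentum
option); held-out PSNR ≈ 31–36 dB across seeds, clearing the 30 dB
visual-equivalence bar, with a closed-form oracle guaranteeing a perfect
converter exists.

`experiments.band_information_monotonicity` — a 4-class catalog with one
confusable pair (δ = 0.3, noise 0.02, 64 training and 40 held-out 64×64
scenes); one converter for 850 nm trained on the training split and
frozen; for five classifier seeds, three classifiers (RGB-only,
RGB+actual 850, RGB+predicted 850) are trained for 40 epochs and scored
on the held-out scenes. Typical outcome: RGB-only ≈ 80 % (the pair sits
at chance, the other classes are solved), RGB+actual ≈ 100 %,
RGB+predicted ≈ 80 %.

**Why predicted bands cannot close the gap here.** The simulator makes
the confusable pair *exactly* metameric: the RGB image carries zero
information about which pair member is present. A predicted band image
is a deterministic function of that RGB image, so by the data-processing
inequality it cannot separate the pair either — the MSE-optimal
converter outputs the conditional mean midway between the members'
planted-band values. The ≈20-point gain from the actual band therefore
comes back as an ≈20-point loss under substitution, and the
"substitution costs ≤ 5 points" property is unattainable under these
invariants, which the corresponding test documents by failing. With real
foods the situation differs: visually similar dishes are not
pixel-identical, and a converter can amplify subtle visible cues into
usable band contrast — that is precisely the regime in which the
original study observed a 1.21-point gap. A generator variant with a
small visible-band leak would reproduce that regime but would break the
exact-metamerism invariants this simulator is specified to satisfy.

## Numerical and design choices

- Plain SGD is the reference optimizer for conversion (momentum optional
  and off by default); the analysis CNN defaults to momentum 0.9.
- He initialisation everywhere; float32 parameters and activations.
- PSNR returns +inf on identical images; MAX is fixed at 1.0.
- SSIM uses the reference parameters: 11×11 Gaussian window (σ = 1.5),
  K1 = 0.01, K2 = 0.03, weighted (non-sample) local moments, borders
  cropped to valid windows.
- The train/validation split takes round(n/11) items (≥ 1) for
  validation — 110 items split 100/10 — stratified per class by largest
  remainders; stratification protects the small synthetic classes.
- Scene seeds derive from `(seed, class, repeat)` via `SeedSequence`, so
  datasets are pure functions of (config, seed) and band noise is
  independent across wavelengths.
- RGB images persist as 16-bit TIFF by default so round trips are exact
  to 1/65535; 8-bit PNG is available for viewing.
- Records with unknown calories are kept for classification and excluded
  from estimation (mirroring items whose nutrition facts are
  unavailable); the synthetic generator itself always assigns kcal.

## Known limitations

- The NumPy engine trains small networks on small images; camera-scale
  (640×480, thousands of images, >1000 epochs) runs are out of reach.
- Scene realism is deliberately minimal (flat-spectrum background,
  single blob, no texture); accuracy numbers on synthetic scenes do not
  transfer to real photographs.
- Stepwise selection offers no global-optimality guarantee for
  interacting objectives.
- The substitution experiment's negative result is a property of exact
  metamerism, as discussed above, not evidence against conversion on
  real data.
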