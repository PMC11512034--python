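# Methods

## Problem and model

The package classifies the adulteration level of a powdered spice from a
single visible-light photograph. Five classes correspond to adulterant
mass fractions w ∈ {0, 0.05, 0.15, 0.30, 0.50}; class indices 1..5 map to
these levels in that order. The physical premise is optical mixing: a
powder blend images approximately as a convex combination of the two pure
powders' reflectances, so per-channel image means shift linearly with w
(brightness up, saturation down for a light, weakly chromatic adulterant),
while grain-scale texture changes nonlinearly. The pipeline therefore
extracts both first-order color statistics and co-occurrence texture from
many color representations and lets feature selection find the efficient
subset.

## Synthetic image generator

The generator emulates the imaging campaign rather than any particular
camera. An image is built as:

1. **Grain tessellation.** A jittered-grid Voronoi partition with cell
   pitch `grain_scale` (default 6 px at 256×256). This gives irregular,
   seedable grains whose characteristic diameter — and hence the GLCM
   texture — is controlled by one parameter.
2. **Composition.** Each grain is adulterant with probability w,
   independently; grain color = palette mean + per-grain Gaussian jitter
   (`rgb_jitter_sd`, default 0.05 per channel; 0.03 for the smoother
   mineral), clipped to [0, 1].
3. **Illumination.** A smooth multiplicative field 1 + f, with f a
   Gaussian-filtered noise surface (σ = min(H, W)/4) normalized to zero
   mean over the frame and peak amplitude `illumination_gradient`
   (default 0.05). Zero-mean normalization keeps the image mean an
   unbiased estimate of the mixture mean, so the convex-combination
   property holds to within grain-sampling noise.
4. **Sensor noise.** Additive i.i.d. Gaussian noise (sd 0.01), then a
   final clip to [0, 1] — clipping rather than renormalizing mimics
   sensor saturation.

Default palettes: black pepper (0.55, 0.46, 0.33) and red pepper
(0.62, 0.37, 0.10) anchor to measured pure-powder means; the sea-foam mean
(0.87, 0.85, 0.82) is a calibration default obtained by extrapolating the
observed brightening of 50% blends to w = 1, not a measurement. With these
palettes the simulated gray mean runs ≈ 0.47 → 0.66 across the five levels.

**What the simulator does not model** — and hence what passing tests do
not show about real photographs: specular highlights, inter-grain shadows
and packing density, chromatic camera response, JPEG artifacts, moisture
or particle-size variation between batches. Simulated classes are cleanly
separated in mean color, so classifiers typically reach 100% on synthetic
data; real-photograph studies of this design report 94–98%. The synthetic
campaign validates the machinery (feature definitions, selection and
training protocols, metric arithmetic), not field performance.

## Channel decomposition

Given R, G, B ∈ [0, 1] and s = R+G+B: gray = 0.2989R + 0.5870G + 0.1140B
(BT.601 luma; the weights sum to 0.9999, which matters only below 1e-3);
HSV by the standard hexcone with H, S, V all on [0, 1]; L\*a\*b\* from sRGB
under D65 (L\* ∈ [0, 100]); chromaticities NR, NG, NB = R/s, G/s, B/s with
the black-pixel convention NR = NG = NB = 1/3 at s = 0; Ohta components
I1 = s/3, I2 = (R−B)/2, I3 = (2G−R−B)/4; and the mean-offset opponent
planes Cr = R − s/3, Cg = G − s/3, Cb = B − s/3 (summing to 0 by
construction). Hue is treated as a plain scalar plane when statistics are
computed; its circularity is deliberately ignored so all 19 channels pass
through one uniform code path. Cropping keeps the centered
`keep_fraction` window (floor dimensions, top/left bias on odd remainders).

## Features

Each channel yields 14 statistics in a fixed order (mean, min, max,
median, mode, std, cv, skewness, kurtosis, energy, entropy, contrast,
correlation, homogeneity), named `<stat>_<channel>`; 19 × 14 = 266.

Numerical conventions: std uses n−1; skewness m3/m2^1.5 and kurtosis
m4/m2² use 1/n central moments (non-excess kurtosis: Gaussian → 3); mode
is the center of the argmax bin of a 256-bin histogram over the plane's
native range (ties to the lowest bin), reflecting 8-bit provenance; cv,
skewness and kurtosis are defined as 0 on zero-variance planes. Entropy
is first-order Shannon entropy (bits) of the 256-bin histogram — observed
gray-entropy values near 7.5 bits only fit this 8-bit-histogram scale, not
a small-level GLCM entropy, which fixes the interpretation.

GLCM: the plane is quantized to 8 equal-width levels over its own
min–max range (per-image range keeps texture features
illumination-robust — an assumption), pair counts are accumulated over
distance-1 offsets in the four standard directions into one shared
matrix, symmetrized and normalized. Energy, contrast and homogeneity are
the usual quadratic forms; correlation uses the marginal moments and is
defined as 1 when a marginal is degenerate (a constant plane is perfectly
predictable). A constant plane with no valid pairs puts all mass at
(0, 0).

## Feature selection

Forward search under a cross-validated deviance: for a candidate subset,
z-score the features on the training folds, fit intercept + linear least
squares to the one-hot class indicators, and average the held-out residual
sum of squares over 5 stratified folds. A feature is accepted only if it
lowers the criterion by more than a relative tolerance (1e-6); search
stops at no-improvement or `max_features` (default 20, bracketing the
17–18 efficient features such studies report). Ties break to the lowest
feature index, and folds are fixed by the seed, so selection is fully
deterministic. The trajectory of accepted criterion values is
non-increasing by construction.

## Classifiers

**ANN.** One hidden layer; tansig on both hidden and output units; MSE
against 0/1 one-hot targets; prediction by output argmax. Training is
full-batch Adam (lr 0.02, default 400 epochs) with early stopping: the
epoch with minimum validation MSE is kept and training halts after
`patience` (30) epochs without improvement. The optimizer is an
implementation choice — the contract is "minimize MSE with validation
early stopping", and any optimizer meeting it is equivalent for the
protocol; Adam is robust at these tiny problem sizes. The sweep trains
hidden sizes 1..20 on a stratified 60/20/20 split and selects by maximum
overall CCR, then lower validation error, then smaller hidden layer.

**SVM.** K(K−1)/2 binary soft-margin RBF classifiers (C = 1000, solver
tolerance 1e-7) on a stratified 80/20 split; prediction by majority vote,
ties broken by the largest summed |decision value| and then the lowest
class index. Default kernel width γ = 1/(n_features · mean feature
variance of the standardized training set) ≈ 1/n_features — an assumption,
as is mapping the toolbox-style parameters (lambda → solver tolerance,
c → penalty C).

Both classifiers standardize features with training statistics, making
them invariant to affine rescaling of individual features.

## Evaluation scopes

Headline confusion matrices in studies of this design are printed over
all N samples even when a test split exists, so the pipeline reports both
scopes: full-set ("paper-style") and held-out test. Degenerate 0/0 metric
ratios are defined as 100 so a perfect matrix scores 100 everywhere.
Percentages are rendered with explicit rounding semantics
(`format_pct`): round-half-up and truncation both occur in printed tables
(88/90 appears as 97.77 truncated and 97.8 rounded), so both are exposed.

## Problem sizes and runtime choices

The default experiment (90 images at 256×256, sweep 1..20) runs in about
half a minute on one CPU; `scripts/acceptance.py` uses exactly these
defaults. The test suite exercises the same code paths at reduced sizes
chosen as the smallest that keep every contract observable: 64–112 px
images, 4–10 images per level, and abbreviated sweeps; the end-to-end
recovery test uses 10 images per level at 112×112 with hidden sizes
{4, 10, 16}. Stratified splitting requires at least one test sample per
class, so five-level configurations need ≥ 5 test samples.

## Known limitations

- The efficient-feature counts of the original photographic study (17 and
  18) are not reproducible on synthetic data; the stopping rule behind
  them is not published, and the counts depend on the photographs.
- Validation-error curves and output–target correlations are
  data-dependent diagnostics, logged but not asserted.
- Hue statistics ignore circularity; a hue distribution straddling 0/1
  will report a misleading mean and variance (harmless for pepper hues
  near 0.1, which stay far from the wrap point).
- The generator's grains are single-scale Voronoi cells; real powders have
  polydisperse, partially transparent particles.
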