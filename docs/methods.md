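# Methods

This note documents the models, conventions and design choices behind
histofusion, in the order the pipeline runs.

## Enhancement

Three stages in fixed order, all arithmetic in float64, quantized to
8-bit once at the end of the chain (minimizing rounding loss).

**Gray-world balance.** Each channel is multiplied by
(global mean / channel mean) and clipped to [0, 255]. The gray-world
assumption — the average scene color is neutral under white
illumination — is a reasonable first-order stain-cast correction but is
*not* a stain normalization (no Macenko/Vahadane deconvolution). An
all-black channel cannot be rescaled and is skipped with a warning.

**Averaging filter.** The default window is 4×4 (16 pixels) with the
center pixel excluded, so each output pixel is the mean of its *N* = 15
neighbors. An even window has no central anchor: we place the nominal
center at position ((h−1)//2, (w−1)//2) of the window, i.e. one
row/column in from the window's top-left center block. A conventional
3×3 / *N* = 9 mode is available. Borders use reflection padding
(symmetric, edge-inclusive), which avoids dark halo artifacts.

**CLAHE.** Per-tile clipped-histogram equalization with bilinear
interpolation between tile mappings, delegated to
`skimage.exposure.equalize_adapthist`. Defaults: 8×8 tiles, clip limit
0.01 (fraction of tile pixel count), 256 gray levels. The equalization
is applied to the CIELAB lightness channel with chroma preserved; a
per-RGB-channel mode exists but shifts hue and is off by default. A
constant image is returned unchanged — the degenerate histogram maps to
the identity — rather than letting the library rescale it to full range.

## Handcrafted descriptors

Grayscale conversion uses luminance weights 0.2989/0.5870/0.1140 and
keeps float precision.

**DWT (12).** Single-level 2-D Haar decomposition (PyWavelets,
orthonormal filters, so the LL of a constant image *c* has mean 2*c*
and total coefficient energy equals pixel energy to 1e-9). Odd image
dimensions are cropped by one pixel rather than padded, keeping the
transform exactly orthogonal. Output order is fixed: [mean, variance,
std] for LL, LH, HL, HH. Variances are population (ddof = 0).

**LBP (203).** Codes follow the thresholded-difference sum with
*s*(0) = 1 (ties count as set bits — the standard convention; a constant
neighborhood yields the all-ones code 2^P − 1). *P* = 15 neighbors are
sampled counter-clockwise from angle 0 on a radius-*R* circle with
bilinear interpolation; interpolated values are rounded at 1e-8 so ties
against the center are exact. The radius is configurable with default
*R* = 2: fifteen samples on a radius-1 ring would oversample the 8-pixel
neighborhood. 2^15 distinct codes cannot be histogrammed directly at a
useful density, and no standard pattern taxonomy yields 203 bins, so
codes are binned into 203 equal-width bins over [0, 2^15 − 1]; the bin
count is configurable. Histograms are normalized to unit mass over the
valid (interior) pixels.

**FCH (16).** Bin centers default to seeded fuzzy c-means (*m* = 2,
seeded initialization from distinct lattice points, tolerance 1e-8) run
on a fixed 4×4×4 RGB lattice of cell centers — a deterministic function
of the seed alone, so every image in a dataset shares the same bins.
Pixel memberships follow the standard FCM update,
u_k ∝ (1/d_k²)^{1/(m−1)}, with the limit convention that a pixel exactly
at a center (d = 0) belongs fully to that center (mass split evenly on
exact multi-center ties). The histogram is the mean membership vector
and sums to one by construction.

**GLCM (13).** Gray levels quantized uniformly to 8 levels (Haralick's
common default; the level count and distance *d* = 1 are configurable).
Offsets use matrix coordinates matching scikit-image's angle convention;
each pair is counted in both directions (symmetric) and normalized. The
13 classical statistics (ASM, contrast, correlation, variance, inverse
difference moment, sum average/variance/entropy, entropy, difference
variance/entropy, and the two information measures of correlation) use
log base 2 with 0·log 0 = 0; correlation and IMC1 return 0 when their
denominators vanish (single-level images). Sum variance is computed
about the sum average (the historical formula's reuse of sum entropy is
a known erratum). Features are averaged over the four angles — the
printed 13-dim output admits no per-angle concatenation.

The combined handcrafted vector is the fixed-order concatenation
[DWT 12 | LBP 203 | FCH 16 | GLCM 13] = 244, with per-column provenance
in `feature_names`. The whole enhanced image is treated as the region of
interest; no segmentation stage exists in this design.

## Deep features

The backbone adapter contract requires only a deterministic
`extract(image) → vector` of fixed dimension (default 4096). The
shipped pseudo-backbone is a seeded random two-stage convolutional
feature extractor (24 then 32 kernels, ReLU, 2×2 max pooling,
implemented as im2col matrix products), global average pooling of both
stages' maps, and a seeded random projection to the output dimension.
Global average pooling of *C* maps yields only *C* values, so a fixed
projection — not a pooling layer — reaches 4096; the adapter contract
deliberately promises only the output dimension, not any internal
architecture. Random features of this kind preserve class-relevant
image statistics well enough for the downstream PCA + classifier stages,
which is their entire role here; wrapping a real pretrained network
behind the same contract is supported but never required.

## Reduction and fusion

PCA is covariance PCA via SVD of the centered training matrix; no
per-feature standardization by default (an explicit standardization step
precedes PCA in the end-to-end pipeline, where descriptor families mix
scales). Components are sign-fixed (largest-|loading| positive) for
bit-reproducible bases; explained variances use the unbiased (n − 1)
normalization so their full-rank sum equals total variance. PCA is
fitted on the training split only — fitting on pooled data would leak
test information into the basis. Requested component counts (455
per-branch, 740 merged) are configuration defaults capped at
min(n_train − 1, dim) for small synthetic runs.

Fusion strategies operate on row-aligned branches: `merge_after_pca`
concatenates per-branch PCA scores (910 at reference settings);
`merge_before_pca` concatenates raw branches then fits one basis (740);
`cnn_plus_handcrafted` concatenates the PCA-reduced deep branch with the
raw handcrafted branch (699), scaling each branch to unit overall
variance on training statistics so 455 deep columns cannot drown 244
handcrafted ones.

## Classifier

One hidden layer of 20 tanh units and 5 output neurons. The "20 hidden
layers" phrasing in the source literature is read as 20 hidden *units*
in a single layer — the accompanying diagnostics are those of a shallow
toolbox network, and 20 stacked layers of unspecified width is not
trainable as described; depth is nevertheless configurable. Both
objectives are implemented: cross-entropy with softmax outputs (default)
and MSE with logistic outputs. Initialization is seeded uniform
±1/√fan_in; training is deterministic full-batch gradient descent with a
bold-driver step rule (grow 5% on improvement, halve and revert on
regression), chosen over stochastic optimizers so histories are
bit-reproducible. Stopping: 6 consecutive epochs without a new best
validation loss (max_fail = 6), gradient norm below 1e-6, or the epoch
budget; returned weights are from the best-validation epoch. Analytic
gradients of both losses are verified against central finite differences
at 1e-5 in the tests.

Diagnostics mirror standard training reports: per-epoch train /
validation / test loss, gradient norm and validation-failure counts; a
20-bin histogram of (target − output) errors whose edges span the pooled
observed range with counts reported per split; and the regression R —
the Pearson correlation between flattened one-hot targets and network
outputs, as a percentage.

## Evaluation

The 5×5 confusion matrix (rows true, columns predicted, classes in fixed
alphabetical order colon_aca, colon_bnt, lung_aca, lung_bnt, lung_scc)
is reduced one-vs-rest per class. Per-class "accuracy" is the binary
accuracy of the reduced 2×2 problem — the only reading that yields five
distinct per-class accuracy values. Ratios with zero denominator are
reported as absent (None), never coerced. AUC is the standard
one-vs-rest ROC area computed as the Mann–Whitney pair statistic from
midranks (ties credit ½), which equals trapezoidal integration of the
threshold-sweep ROC curve; a literal TP-rate/FP-rate ratio is not an
area and is deliberately not implemented. Macro averages are unweighted
means over the five classes; report rounding (2 decimals, half-up)
happens at display only.

The stratified split takes per class floor(n·0.2) test samples, then
floor(0.2·rest) validation from the remainder; the rest trains. For
5000 per class this gives 3200/800/1000 — the three splits partition
each class exactly. Records are shuffled per class under the given seed
before slicing, so the split is a pure function of (manifest order,
fractions, seed).

## Synthetic data

The generator emulates the two axes real H&E histology classes differ
on: stain color statistics and texture regime. Five texture families
(glandular blobs, smooth, stripes, speckle, checker) are paired with
five base colors in the magenta/pink stain range. A single
`separability` parameter in [0, 1] linearly interpolates every class
parameter between a common neutral spec (identical distributions →
chance-level classification) and the fully distinct targets; pattern
amplitude scales with separability, per-image color jitter has σ = 6,
pixel noise σ = 10, patterns have 5–8 px periods, and amplitude 40 at
full separability. Defaults: 100 images/class at 64×64 — the full
pipeline runs in seconds at this scale. Per-image seeds derive
arithmetically from (dataset seed, class, index), making regeneration
byte-identical.

What passing tests show — and do not. The synthetic classes carry
signal for each descriptor family by construction, so the recovery test
(≥95% at separability 1, chance at 0) validates the *mechanics* of the
chain: descriptors respond to their intended image structure, PCA and
fusion preserve it, the classifier and early stopping work, and the
whole chain is leak-free (the zero-separability run confirms accuracy
collapses to chance rather than being inflated by any split or fitting
leak). It says nothing about accuracy on real histology, which differs
in nucleus-scale morphology, stain variability and intra-class
heterogeneity no 64×64 parametric texture reproduces.

## Numerical conventions and degenerate inputs

Histogram outputs sum to 1 within 1e-9. Haar energy conservation holds
to 1e-9, full-rank PCA reconstruction to 1e-8, component orthonormality
to 1e-8. LBP interpolation rounds at 1e-8 before thresholding so exact
ties behave identically in vectorized and per-pixel paths. Constant
images: identity under CLAHE and the full enhancement chain; all-ones
LBP code; single-cell GLCM with ASM 1, contrast 0, entropy 0;
correlation defined as 0. Feature matrices refuse non-finite entries at
construction and at save time.

## Known limitations

No stain normalization or ROI segmentation; single-level Haar only;
rotation-invariant/uniform LBP variants and per-angle GLCM features are
out of scope; the pseudo-backbone is a deterministic random-feature
extractor, not a trained network, so absolute deep-branch accuracy on
real data is meaningless; full-batch training assumes the feature matrix
fits in memory (true up to ~25k × 910 at float64).
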