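# Methods

This note documents the models and procedures implemented in `irispad`,
the parameters that matter, the synthetic data the package is validated
on, and the design decisions taken where the problem left genuine
freedom.

## Segmentation

**Pupil template matching.** Under NIR illumination the pupil absorbs
more light than iris, sclera or skin, so it appears as the darkest
region. The detector scans block size `s` over
`[image_height/20, image_height/5]` in 4-px steps and positions `(x, y)`
at a configurable stride (default 2 px, with a stride-1 refinement pass
around the coarse argmax), scoring each candidate by
`Σ_{i=1..8} (U_i − U_0)` over a 3×3 tiling of s×s blocks and requiring
`U_0 < U_i` for every neighbor. Block means are exact rectangle queries
on an int64 summed-area table. Ties break toward the smallest block,
then lexicographic (y, x), so results are reproducible. If no block is
strictly darker than all eight neighbors (e.g. a uniform image) the
detector raises a detection failure rather than guessing.

**Circular edge detection.** Boundaries are refined by maximizing the
absolute radial derivative of the mean intensity along a circle.
Candidate centers are the pixels inside the detected pupil block
(stride 2 by default); radii are swept on a unit-px grid. The radial
profile is smoothed with a Gaussian of sigma = 1 radius-step before
central-difference differentiation — classical practice for
integro-differential localizers, which are otherwise noise-sensitive.
The *absolute* derivative is used so both dark→light (pupil→iris) and
light→dark edges count. Contour means use 256 equi-angular bilinear
samples per full circle, scaled by arc fraction (midpoint sampling, so
symmetric scenes average exactly). The pupil uses the full circle; the
iris restricts the contour to −45°…+30° and 150°…225° (measured CCW
from +x; image y is inverted accordingly), the left/right iris–sclera
boundary segments that eyelids and lashes rarely occlude. The iris
radius search starts at 1.1× the found pupil radius, enforcing the
pupil-inside-iris ordering with a margin.

**ROI.** The square of side 2·(iris radius) centered on the iris is
cropped (edge-padded where it leaves the frame), bilinearly rescaled to
224×224, and duplicated into three identical channels for the network.
Whether the crop should include margin beyond the iris circle is not
fixed by the problem; side = 2r (no margin) is this package's choice.

## Multi-level uniform LBP

Each pixel is encoded against P neighbors on a radius-R circle,
`bit_i = 1 ⟺ g_i ≥ g_c`, with sample i = 0 at angle 0 proceeding CCW and
weight 2^i. Neighbors off the lattice are bilinearly interpolated; the
interpolation is evaluated in the form `a + f·(b − a)`, which makes the
codes — and hence the whole descriptor — *exactly* invariant to adding
a constant to the image, not merely up to rounding. Codes with ≤ 2
circular bit transitions are uniform and get individual bins (ordered
by code value); the rest pool into one non-uniform bin, giving
P(P−1)+3 bins per level. Pixels within ceil(R) of the border are
skipped (padding would fabricate edge codes). Histograms are
L1-normalized per level by the number of encoded pixels, making them
comparable across ROI sizes; z-scoring downstream removes the remaining
scale freedom.

The default grid is seven levels: P=8 at R∈{1,2,3} and P∈{12,16} at
R∈{2,3}, totalling 3·59 + 2·135 + 2·243 = 933 dimensions. R=1 is
excluded for P ≥ 12 because the neighbor spacing would drop below one
pixel and adjacent samples would interpolate from the same cells. The
rotation-invariant (riu2) mapping is deliberately not offered — the
dimension formula P(P−1)+3 is that of the non-rotation-invariant
uniform mapping, and attack artifacts (printing dots) are not
rotation-structured anyway.

## Convolutional features

The full network is a VGG-19-shaped stack: conv groups of 2-2-4-4-4
3×3/stride-1/pad-1 layers with 64/128/256/512/512 filters, 2×2 stride-2
max-pooling after each group, then fully-connected layers of
4096/4096/2 units with ReLU and dropout 0.5 on the first two. From a
224×224×3 input the conv stack ends at 7×7×512 = 25,088 activations;
the second fc layer's 4096 activations are the deep feature. The
feature is taken *after* that layer's ReLU (dropout inactive at
inference): "activations" most naturally means post-nonlinearity, and
non-negative features also behave better under z-scoring.

Training is SGD with momentum 0.9, batch 32, initial learning rate
0.001 multiplied by 0.1 every 3 epochs, 9 epochs total, cross-entropy
loss, seeded He-style initialization. A weight-loading hook accepts
externally supplied initial weights (e.g. an ImageNet-pretrained
checkpoint); none are shipped, and initialization quality is an
optimization concern, not a correctness requirement of the pipeline.

The backend is plain NumPy. Convolution is evaluated as nine shifted
matrix products (one per 3×3 tap), which is exact, simple to
differentiate, and fast enough at desk scale. The full 19-layer network
is constructed and shape-verified but never trained in the test suite;
training runs on a **reduced spec** with the same structural grammar:
two conv groups (8 and 16 filters), fc widths 512/512/2, square
3-channel input (64 px when constructed directly; the pipeline feeds
96-px inputs — the 224-px ROI is itself upsampled from a ~60–90 px
native iris crop, so ~96 px preserves the native detail scale,
including the ~2-px printing raster that downsampling to 64 px would
alias away).
Two reduced-spec choices matter and were settled empirically:

* **Input centering.** Inputs are mapped to `(v/255 − 0.5)·4`. With the
  short step-decayed schedule (~63 SGD updates on a 200-image set) an
  uncentered [0, 1] input leaves first-layer gradients dominated by the
  DC component and training sits at chance; centering fixes it.
* **No dropout in the reduced spec.** Dropout 0.5 regularizes the full
  network's 4096-wide layers against overfitting a 50k-image training
  set. At desk scale it only injects gradient noise that a handful of
  updates cannot average out — with it, training accuracy varies wildly
  across seeds; without it, the reduced net fits its training set
  (≥ 0.985 accuracy on every seed tested). The full spec keeps
  dropout 0.5.

## Fusion and classification

Feature-level: each block (CNN first, MLBP second) is z-scored with
training-set statistics — population standard deviation, with a floor
that maps sd < 1e-8 to 1 so constant dimensions pass through centered —
concatenated (5029-d at full scale), reduced by PCA, and classified by
one kernel SVM. PCA keeps k = min(512, n_train − 1, dim) components; the
512 cap applies to single-feature subsystems as well. PCA is fit after
z-scoring (the natural order: PCA on raw concatenated blocks would be
dominated by whichever block has larger numeric range).

Score-level: each feature type drives its own z-score → PCA → SVM
subsystem. Raw SVM decision values are mapped to [0, 1] attack
probabilities by a Platt-style logistic fitted on training decision
values (Nelder–Mead on the calibration log-loss). The fused score is
S = w₁S₁ + w₂S₂ with w₁ + w₂ = 1, w₁ grid-searched over {0, 0.01, …, 1}
for best training accuracy at the 0.5 threshold; ties break toward
w₁ = 0.5 and then toward smaller w₁, so the selection is deterministic.

SVM hyperparameters are not dictated by the problem; defaults are
C = 1, γ = 1/dim, coef = 1, degree = 3, configurable per subsystem
(linear / RBF / polynomial kernels). The attack class is positive
everywhere: higher score = more attack-like.

## Evaluation

APCER = % of attacks with score < threshold (accepted as bona fide);
BPCER = % of bona-fide presentations with score ≥ threshold (rejected).
Samples exactly at the threshold classify as attack — a fixed boundary
rule chosen for reproducibility. ACER is the arithmetic mean. The
operating point is the calibrated 0.5 threshold; DET curves sweep the
threshold over all observed scores and report APCER against
BPAR = 100 − BPCER. Multi-split protocols (same-sensor "known" and
cross-sensor "unknown" test sets) are summarized by the
sample-size-weighted average of per-split ACERs.

## Synthetic data

The generator emulates the structure segmentation and texture analysis
rely on: a dark pupil disc (intensity 30), an iris annulus (base 110)
carrying a sum of 3–6 random-phase sinusoids in polar coordinates
(amplitude 25), a brighter surround (200) — the pupil < iris < sclera
NIR ordering — and a spatially smooth capture-shading field (sd 3,
low-passed at σ = 1). The noise field is deliberately *not* per-pixel
white: a live capture varies in illumination but keeps its fine texture
clean, and pixel-level white noise would flood the non-uniform LBP bins
of the bona-fide class, inverting the very statistic that separates
attacks. Default geometry is a 160×120 frame with pupil radius 10–16 px
and iris radius 30–45 px; tests and the acceptance checks run at this
size so the whole suite stays within desk-scale runtimes, and nothing
in the pipeline depends on the frame size.

Attack variants model a print-and-recapture chain, in order: Gaussian
blur (σ = 1; detail lost in the printed pattern), 4-level quantization
of the iris annulus (the print's limited tonal depth — "broken
texture"), fresh capture shading noise (the attack is recaptured by the
same sensor, so its noise floor matches a live capture's; applied only
when blur is active so disabling every transform yields the identity),
and finally salt-like bright dots (density 0.03) — the printing raster,
observed sharply on top of the recaptured pattern. With this chain the
attack class carries strictly more non-uniform LBP mass than its
bona-fide source, the artifact structure the descriptor is designed to
detect. An "unknown-style" dataset regenerates attacks with doubled
blur to emulate a cross-sensor shift. An optional eyelid band (off by
default) exercises the arc-limited iris detector.

What passing on synthetic data shows — and what it does not: the
synthetic eyes validate the *mechanics* (geometry recovery, descriptor
arithmetic, fusion and metric computation, end-to-end separability of a
strongly artifacted attack class). They do not model specular
highlights, gaze, eyelashes, sensor-specific noise, or the subtle
texture statistics of real printed/lens attacks, so error rates
measured here say nothing quantitative about performance on real PAD
benchmarks.

Training-set augmentation follows the field's protocol of 14 variants
per bona-fide image and 8 per attack (balancing the classes): the
bona-fide plan is 8 compass shifts of ±5 px, 4 corner crops at fraction
0.9 rescaled back, and scalings at 0.95/1.05; the attack plan is the 8
shifts. The transform families and counts are protocol facts; the
magnitudes are this package's fixed choices, making the counts (15a+9b
total images) exactly reproducible. Shifted images are edge-replicated
rather than zero-padded so LBP never sees an artificial dark border.

## Numerical notes and limitations

* Integral-image sums are exact (int64) for integer-valued images.
* All argmax searches have explicit deterministic tie-breaks.
* Every stochastic component (generator, CNN init/shuffling/dropout)
  draws from a seeded generator; fixed seeds give bit-identical runs.
* The pupil detector assumes the darkest-region-is-pupil property;
  strong shadows or dark frames violate it and raise detection
  failures rather than silently mislocating.
* Circle recovery is validated to 2-px accuracy on ≥ 95% of noiseless
  synthetic eyes; heavy texture or occlusion degrades the arc-limited
  iris estimate first.
* The NumPy CNN is single-threaded apart from BLAS matmuls and is not
  intended for full-scale (224×224, 19-layer) training; the full
  architecture exists for structural fidelity and shape verification.
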