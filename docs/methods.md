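# Methods

This note records the models implemented in `ctinfarct`, the parameters
that matter, and the design decisions taken where the method left room.

## Intensity transformation

Raw CT attenuation is mapped by a continuous piecewise-linear function
with breakpoints at −100 and 100 HU:

| input HU        | map           | output range |
|-----------------|---------------|--------------|
| [−1000, −100]   | HU + 1000     | [0, 900]     |
| (−100, 100]     | 11·HU + 2000  | (900, 3100]  |
| (100, 1000]     | HU + 3000     | (3100, 4000] |

The middle segment is the unique line through (−99, 911) and (100, 3100);
it is continuous with both neighbours at the breakpoints and magnifies
soft-tissue contrast 11-fold, which is the point of the transformation:
an 8–20 HU ischemic hypodensity becomes an 88–220-unit drop. The map is
strictly increasing and exactly invertible on integer HU in
[−1000, 1000]. Inputs outside that range are clamped first — real headers
contain −1024 air padding, and rejecting it would be needlessly brittle.
Non-integer HU go through the same continuous map.

## Skull/CSF elimination

The mean and sample SD (n−1 denominator) of all strictly positive
transformed voxels define thresholds mean ± 2·SD: below → ventricle/CSF,
above → skull, ties stay in the parenchyma. Zero-background exclusion is
deliberate: template-space volumes have zero-filled out-of-field
exteriors, which would otherwise dominate the statistics. No
morphological cleanup is applied. The returned volume equals the input on
the parenchyma and is exactly 0 elsewhere, and the three masks partition
the positive-voxel set.

On the digital phantoms this step reliably removes the skull but *not*
the ventricles: with CSF at 0 HU and parenchyma at 25–35 HU the CSF level
(2000 transformed) sits well inside mean − 2·SD unless the skull occupies
under ~1 % of the head, which no plausible geometry achieves. Ventricle
tiles therefore survive into tiling on phantoms; they carry t ≈ 0 (the
controls have the same ventricles) and are learned as non-infarcted. The
ventricle branch of the rule is exercised by constructed-volume tests
with genuinely outlying fluid values.

## Gaussian smoothing

Separable stationary Gaussian, σ per axis = (FWHM / 2√(2 ln 2)) /
voxel size; default FWHM 5 mm. Smoothing is *normalized over the mask
support* (smooth(masked data) / smooth(mask), evaluated on the mask):
after skull stripping, plain convolution would mix zeros into the brain
edge, darken it, and mimic an infarct rim. Plain convolution is available
via `normalize=False` for compatibility with pipelines that smooth the
full grid. Normalized smoothing preserves constants exactly and conserves
impulse mass on a full mask.

## Normative model and t-scores

Controls are preprocessed (transform → eliminate → smooth) and summarized
voxel-wise by mean X̄_C and sample SD s_C (n−1). A patient voxel p gets
the Crawford–Howell single-case statistic
t = (p − X̄_C) / (√((n+1)/n)·s_C), where the correction factor accounts
for the uncertainty of a mean and SD estimated from a finite cohort
(n = 38 in the reference design). Implementation guards:

* voxels with s_C < ε (ε = 1e−6) are excluded from the t-map mask rather
  than mapped to ±∞ — identical-control cohorts otherwise produce NaN;
* the t-map is only valid on parenchyma ∩ {≥2 nonzero control
  contributions}; off-mask t is stored as 0;
* signed t is used throughout (hypodense lesions are negative); no
  absolute value is taken before classification.

## Patch extraction and augmentation

Axial slices are tiled by a non-overlapping 16×16 grid anchored at (0,0);
only complete tiles are produced and a tile is adopted only if *every*
pixel lies in the t-map mask. (The area quotient 181·217/256 ≈ 153 per
slice is an upper-bound estimate; the number of complete disjoint tiles
on the full grid is 11·13 = 143.) A tile is labeled infarcted when it
overlaps the lesion ground truth in ≥ `min_lesion_pixels` pixels
(default 1, configurable because single-pixel labels are noisy).

Augmentation re-cuts each adopted patch shifted by `shift_pixels`
(default 4, a quarter patch — large enough to change the content,
small enough to preserve the label most of the time) along the 8 compass
directions; a candidate is rejected if it leaves the mask or if
relabeling flips its class. Class balancing keeps the minority class and
subsamples the majority to 1.1× the minority (seeded, order-invariant);
the train/validation split is a seeded uniform 80/20 partition with
round-half-up train size, repeatable k times for cross-validation.

## The classifier

A 17-layer CNN: input, three blocks of (3×3 convolution, stride 1, same
padding → batch normalization → ReLU → 2×2/2 max pooling) with 8/16/32
filters, a fully connected layer to 2 classes, dropout 0.5, softmax, and
a cross-entropy classification output. Spatial size shrinks 16→8→4→2, so
the head sees 128 features. Kernel size, filter counts, padding and
dropout placement are package choices; the layer enumeration is asserted
structurally in the tests.

Because no neural-network framework is part of the dependency set, the
network is implemented directly in NumPy — im2col convolutions (backward
pass as a convolution with the flipped, channel-transposed kernel),
exact batch-norm backprop, inverted dropout — and verified against
central finite differences in the test suite. Arithmetic is
single-precision; BLAS matmuls make CPU training practical
(~0.16 s per 500-patch iteration).

Training is SGDM: momentum 0.9, mini-batch 500 (partial final batches
used), L2 weight decay 0.005 on weights (not biases or batch-norm
parameters), caps of 1000 epochs / 8000 iterations, learning rate
decaying geometrically per epoch from 1e−5 to 1e−7 across the planned
run. Two conventions were genuinely open and are fixed as follows:

* **Loss reduction is a sum over the mini-batch**, not a mean. With batch
  500 this makes the 1e−5 initial rate an effective per-sample step of
  5e−3; under mean reduction the same printed schedule moves the weights
  by ~1e−5 per step and learns nothing in 8000 iterations.
* **The decay path is geometric per epoch** between the stated endpoint
  rates (a piecewise-constant alternative is available via
  `lr_schedule="constant"`).

Inference disables dropout and uses batch-norm running statistics, so
prediction is deterministic; the class decision is the softmax argmax.

## Digital phantoms

Phantoms emulate template-space head CT: nested ellipsoids (skull shell,
gray-matter shell, white-matter core, two lateral ventricles) with tissue
means CSF 0 / WM 25 / GM 35 / bone 1000 HU, per-subject tissue-mean
jitter (SD 1 HU) for biological variation, and additive Gaussian voxel
noise (SD 3 HU) confined to the head — the exterior is flat −1000 HU,
emulating the zero-filled out-of-field background that spatial
normalization leaves, so it maps to exactly 0 and stays out of the
whole-brain statistics. The skull shell is kept geometrically thin
(~11 % of the head) so that bone is a genuine outlier tail of the
intensity distribution and the 2σ rule removes it.

Lesions are unions of overlapping spheres (default 3 per lesion, radii
6–12 mm) planted wholly inside the parenchyma via a Euclidean distance
transform, with an HU decrement sampled from 8–20 HU — a configurable
modeling choice for an acute-infarct hypodensity, not a measured value.
A sulcus artifact (CSF-filled surface groove) reproduces the known
false-positive mechanism of age-mismatched controls. All generators are
pure functions of (cohort seed, subject seed).

Default grid 91×109×91 at 2 mm — half the linear resolution of the
181×217×181 1-mm template — with the full grid supported; the default
cohort is 38 controls and 21 patients. The end-to-end test trains on 6
patients at half resolution with a 2000-iteration cap, which reaches
~98 % validation patch accuracy, ~99 % lesion-tile sensitivity and a 0 %
control false-positive tile rate under seed 1.

What passing phantom tests do **not** show: performance on real CT.
Phantoms have no beam hardening, streaks, partial-volume gyri, sulcal
CSF, asymmetric anatomy or registration error, and their lesions are
geometric and strongly separated in t; the phantom accuracy figures are
an internal-consistency check of the pipeline, not a clinical claim.

## Numerical conventions

* Axis order (sagittal, coronal, axial); axial slices indexed last;
  0-based, half-open coordinate ranges everywhere.
* Threshold comparisons in the elimination step are strict; ties at
  mean ± 2·SD remain parenchyma.
* Round-half-up for train-set size and percent metrics (one decimal).
* Seeds: every stochastic operation takes an explicit seed;
  subject-level streams derive from `SeedSequence([cohort_seed,
  subject_seed])`, so cohorts are bitwise reproducible on one worker.
* Degenerate inputs raise typed errors (`ContractError`,
  `EmptyInputError`, `GenerationError`, `FormatError`) rather than
  propagating NaN.

## Known limitations

* Spatial normalization (and DICOM writing) is out of scope: inputs are
  assumed to be on the template grid already; DICOM series reading is
  provided for convenience.
* The 2σ elimination does not remove ventricles on phantoms (see above).
* Batch-norm running statistics are momentum-averaged (0.1); very short
  training runs evaluate with partially warmed statistics.
* Atlas lookup ships no atlas content; any integer label volume on the
  template grid with a name table can be supplied.
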