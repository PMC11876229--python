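# Methods

`mammojig` reimplements, end to end and at desk scale, a study design for
breast-cancer classification on mammographic crops: jigsaw-puzzle
self-supervised pretraining of a convolutional encoder, transfer of that
encoder into a binary cancer classifier, and an evaluation protocol built on
patient-grouped repeated cross-validation, Youden operating points, subgroup
metrics and Grad-CAM attention maps. A synthetic phantom generator supplies
data with the statistical structure the protocol needs, so every stage runs
and is verifiable on one CPU without any image download.

## The pretext task

A 512×512 crop is tiled into a 3×3 grid of 170×170 cells (512 = 3·170 + 2;
the two leftover pixel rows/columns are discarded so cells stay equal). An
independent random 150×150 window is drawn inside each cell — the up-to-20 px
slack per axis realises the *random gaps* that prevent the network from
solving the puzzle by matching texture across patch borders. The nine patches
are reordered by one of 31 predefined permutations and the network must
recognise which one.

**Permutation set.** The label space is the identity plus 30 derangements of
{0..8}. Derangements are exactly the permutations at the maximal Hamming
distance 9 from the identity; the 30 classes are selected from a seeded pool
of 2000 random distinct derangements by greedy max-min Hamming dispersion
(ties broken by larger mean distance to the selected set, then by sampling
order). Restricting to derangements fixes the identity-to-class distances at
9; the greedy step controls class-to-class distances. The resulting
mean pairwise Hamming distance over all 465 unordered pairs is ≈ 8.17 with
very small seed-to-seed spread (the statistic the acceptance script reports).
The 133,496 derangements of 9 elements make the "top 30 by distance to
identity" criterion massively tie-broken; max-min dispersion is the
construction that makes the selection well defined and reproducible. On a
2×2 toy grid (4! = 24 orderings, 9 derangements) the greedy selector
provably attains the brute-force optimal dispersion, which the tests verify
by exhaustive enumeration.

**Permutation convention.** Grid slot *i* (row-major) receives the patch
originally at position `mapping[i]`. One convention is used everywhere and is
pinned by an apply-then-invert round-trip test; mixing it with the inverse
convention is the classic off-by-one of jigsaw implementations.

**Per-patch standardization.** Each patch is independently scaled to zero
mean and unit variance (constant patches map to zeros). This removes absolute
brightness as a shortcut for the puzzle; it can be disabled.

## Architectures

The context-free network (CFN) applies **one shared encoder** to each patch,
projects each patch's pooled features through a small fully connected layer
(the per-patch projection of the original CFN formulation; its width is
configurable), concatenates the nine projections in slot order and classifies
the permutation with a final fully connected layer. The downstream classifier
reuses the same encoder architecture on the whole 512×512 crop and ends in a
single cancer logit. Global average pooling makes the encoder input-size
agnostic — that is what lets 150×150-patch pretext weights initialise a
512×512-input classifier without any surgery.

Encoders are small CNNs (three or two conv–ReLU–avg-pool blocks behind a
fixed average-pooling input stage, default factor 8) so that full training
loops run in seconds to minutes on one CPU; they are registered behind an
`EncoderSpec`, and the whole stack — forward, backward, Adam — is a small
NumPy layer (`mammojig.nn`) whose gradients are verified against numerical
differentiation. Deeper encoders can be registered behind the same spec;
large-scale natural-image pretraining is out of scope, and the arms that
assume externally pre-initialised weights accept any checkpoint file (the
package produces one with a brief rotation-prediction pretext on synthetic
crops, which preserves the four-arm comparison structure without claiming
equivalence to ImageNet pretraining).

Every encoder ends in a per-sample feature-standardization layer. Without
it, pilot runs showed the encoder's feature scale drifting during pretext
training, which made short fine-tunes from transferred weights erratic —
occasionally much worse than training from scratch. Normalizing the pooled
feature vector per sample makes transfer invariant to that drift without
introducing batch statistics (so evaluation stays deterministic and
batch-size independent).

Initialization uses two independent seeded streams (encoder vs heads), so a
CFN and a classifier built from the same seed share identical initial encoder
parameters. This gives the exact degenerate equivalence used as a test:
jigsaw pretraining with 0 epochs followed by transfer is bit-identical to
training from scratch.

## Training

Adam with learning rate 10⁻³, weight decay 0, cross-entropy losses; batch
size 128 for the pretext and 64 for fine-tuning; the reference schedule is
100 epochs and every loop scales down by configuration. No learning-rate
schedule, no augmentation beyond the jigsaw jitter, no early stopping. Each
pretext step draws a fresh uniform permutation label and fresh jitter per
image; fine-tuning standardizes whole images before the encoder. All loops
are seeded and deterministic; non-finite losses abort with the epoch index.

**Four arms.** `IN-Jig` (pre-initialised weights → jigsaw pretext →
fine-tune), `Scratch-Jig` (random → pretext → fine-tune), `IN`
(pre-initialised → fine-tune), `Scratch` (random → fine-tune). Within each
cross-validation fold, pretext training uses only that fold's training
images — the strictest reading of patient-level separation from pretraining
through the downstream task. The runner enforces the protocol: a split plan
that leaves any patient without a fold assignment aborts with a protocol
error, since unassigned patients would silently join every training split.

## Evaluation

* **AUC** via the tie-aware ROC (trapezoidal area = Mann–Whitney
  probability); verified against brute-force pair counting up to n = 200.
* **Youden operating point**: candidate cutoffs are the distinct observed
  scores plus +∞, predicting positive at score ≥ cutoff; ties on
  J = sensitivity + specificity − 1 resolve to the smallest cutoff. Verified
  against an exhaustive scan.
* **Subgroups**: per-finding AUC over images with that finding; the normal
  group, which has no positives by definition, reports the normal-TNR (the
  fraction of normal images below the cutoff). Per-density AUCs likewise. A
  subgroup missing a class reports NaN rather than aborting.
* **Mean ROC**: vertical averaging on a fixed 101-point FPR grid with a
  min/max envelope.
* **Splits**: per trial, patients are shuffled with a trial-specific seed and
  dealt round-robin into k folds (sizes within one patient of equal; a
  patient never spans folds).
* **Arm comparison**: two-sided t-test on per-trial AUCs, paired by default
  because arms share trial split seeds (an unpaired variant is available);
  all-zero differences give p = 1, zero-variance nonzero differences report
  the limiting p = 0. 95% confidence intervals over trials are
  mean ± 1.96·SE (a t-quantile alternative would widen them slightly at
  10 trials; the normal approximation mirrors the convention of reporting
  parenthesised intervals over ten trials).

## Grad-CAM

Channel weights are the spatial means of the positive-logit gradient at the
last spatial convolutional block (the standard target; any spatial layer can
be chosen); the CAM is the rectified weighted sum of that block's feature
maps, bilinearly upsampled to the input and max-normalized (all-zero maps
stay zero). A toy network with hand-set weights pins the arithmetic in the
tests. The qualitative study claim — that a trained classifier attends to
the lesion — is tested as a directional property: mean CAM value inside the
lesion mask exceeds the outside mean for the majority of 20 held-out
phantom mass images.

## The synthetic phantom generator

Each phantom crop is a bright tissue field with three ingredients:

1. **Fibrous streaks** radiating from a per-image focus placed just outside
   the crop (product of smooth angular and radial noise profiles in polar
   coordinates about the focus) — a cartoon of ductal structure converging
   on the nipple. Because the focus is close, streak *orientation* varies
   strongly across the 3×3 grid, which is the positional cue that makes the
   jigsaw task solvable after per-patch standardization.
2. **Isotropic parenchymal texture** (smoothed Gaussian noise) plus a smooth
   illumination falloff toward a random off-crop point.
3. **Density**: the dense-breast (DB) category has brighter, higher-variance
   fibroglandular texture and reduced lesion contrast (×0.62), reproducing
   the DB-harder-than-Not-DB structure subgroup metrics are meant to expose.

Lesion classes and their ground-truth masks:

* **Mass** — Gaussian-profile ellipse; mask = ellipse support. Malignant
  masses are eccentric, sharp-edged, higher-contrast and spiculated (radial
  von-Mises bumps on a ring beyond the margin); benign masses are round,
  smooth and fainter.
* **Calcification** — cluster of bright elliptical dots inside a disk; mask
  = the disk. Malignant clusters are tighter, more numerous and irregular
  (elongated dots); benign clusters are sparse and round.
* **Distortion** — local swirl of the background texture (inverse rotation
  map with radius-decaying angle); mask = bounding box, following the
  convention that distortions have ambiguous margins. Malignant swirls are
  stronger.
* **Malignant lesions of every class additionally retract the surrounding
  tissue**: a radial warp pulls fibrous texture toward the lesion before the
  lesion is drawn, emulating the desmoplastic convergence of strands toward
  a malignancy. This places part of the cancer signal in the *orientation
  structure of the surrounding tissue* — precisely the kind of feature the
  jigsaw pretext teaches an encoder to represent, and therefore the
  mechanism behind the transfer-benefit ordering the study investigates.

Mask area fractions are drawn uniformly from per-finding ranges centred on
the reference means (mass 20.7%, calcification 25.2%, distortion 57.5% of
the 512² crop): (0.157, 0.257), (0.202, 0.302), (0.475, 0.675). The
distributional shape within those means is a modelling choice, not a claim
about any real dataset. Default category proportions encode the reference
population exactly (findings 1140/570/60/1054 of 2824; per-finding cancer
rates 954/1140, 508/570, 53/60; density 2377/2824 dense), patients
contribute 1–2 images (two with probability 826/1775), and the seven
exclusion flags fire at their reference rates relative to 2601 images.
Additive Gaussian noise defaults to 600 gray levels of the 16-bit range.
Images are written as 16-bit PNG, masks as 8-bit 0/255 PNG, manifests as
CSV with a fixed column order. Everything is deterministic in
`(config, index)`: per-image generators are spawned from the config seed
and the image index.

Full-field phantoms (default 1024×768) add an MLO geometry: a half-ellipse
breast against the left edge and a brighter pectoral-muscle wedge in the
top-left corner, with ground-truth breast and wedge masks for testing the
segmentation and normal-crop rules.

**What the phantoms do not model**: photorealistic mammographic appearance,
scanner physics, overlapping lesions, CC views, longitudinal structure.
Passing tests show the *pipeline* behaves as specified on data with the
study's statistical skeleton; they say nothing about clinical performance
on real mammograms.

## Preprocessing rules

Exclusions drop exactly the flagged records and report per-flag counts
(conservation: kept + removed = total; the operation is idempotent). Breast
segmentation is Otsu thresholding followed by largest-connected-component
selection, with the outline extracted as the longest boundary contour —
"binarize and take the breast area" with the standard parameter-free
threshold. Lesion crops are 512×512 windows centred on the mask centroid and
clamped to the image bounds (clamping, not padding, keeps every crop made of
real pixels; how border-straddling lesions were handled in the source data
is unknown, so clamping is this package's choice). Normal crops draw their
centre uniformly from pixels that are inside the breast mask, below the top
20% of the breast's row extent (which excludes the pectoral wedge at the top
of an MLO view), and far enough from the borders for the window to fit.
Coordinates are 0-based row/column with half-open windows.

## Desk-scale test conditions

The test suite runs the full stack at reduced sizes, chosen once and frozen:

* label-learnability: a small classifier trained on ≈ 500 synthetic crops
  (22 epochs, batch 16) must exceed AUC 0.8 on held-out crops;
* pretext smoke: a small CFN on a 2-permutation task over ≈ 100 crops must
  exceed 0.9 training accuracy within 30 epochs;
* chance level: an untrained CFN sits at ≈ 1/31 accuracy on the 31-class
  task (4.5σ binomial band at n = 1000);
* directional transfer: over 3 seeded datasets (≈ 300 crops each, 5-fold
  patient-grouped split, one validation fold per seed, 20 pretext +
  20 fine-tune epochs at batch 32), the median validation AUC of
  Scratch-Jig must be at least that of Scratch. This checks the *ordering*
  of the reference comparison, not its magnitudes. The pretext needs
  enough images to learn (a 31-class permutation accuracy well above the
  0.032 chance level); pilots showed that below roughly 200 pretext
  images the transferred features are noise and the ordering is a coin
  flip, while from ≈ 250 images upward the ordering is consistently
  favourable — the same data-volume sensitivity that motivates
  self-supervised pretraining in the first place.

## Numerical choices and degenerate inputs

Softmax cross-entropy subtracts the row max; the logistic loss uses the
log1p(exp(−|x|)) form; sigmoid is evaluated branch-wise — all gradients are
exact and finite for any finite input. Constant images and patches
standardize to zeros rather than dividing by zero. Otsu on a constant image
raises a segmentation error. An empty lesion mask is a precondition error
for cropping. Average pooling drops trailing rows/columns that do not fill
a window. Adam uses bias-corrected moments with ε = 10⁻⁸.

## Known limitations

The NumPy network trains small CNNs only; there is no GPU path, no batch
normalization, no data-parallelism. The rotation-pretext checkpoint is a
stand-in initialization with no claim of equivalence to large-scale
pretraining, so four-arm comparisons on synthetic data probe pipeline
mechanics, not the reference magnitudes. The phantom cancer signal is
intentionally coarse (contrast, dot statistics, spiculation, convergence);
real mammographic malignancy cues are far subtler.
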