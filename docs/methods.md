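# Methods

`crescentseg` reimplements a one-click segmentation pipeline for chronic
subdural hematoma (CSDH) on head CT: slice-wise U-Net segmentation in a 2D
and a 2.5D variant, mirrored test-time averaging, threshold binarization,
covariate-stratified 10-fold cross-validation, and mask-based volumetry.
This note documents the models, the synthetic phantom that stands in for
clinical data, the numerical choices, and the places where the design was
genuinely open.

## The segmentation models

Both variants are a classic U-Net: `depth` levels of double 3x3
convolution + relu blocks with 2x2 max pooling on the contracting path,
nearest-neighbour upsampling, a 3x3 convolution and skip concatenation on
the expanding path, and a final 1x1 projection to two class maps
(background, hematoma) under a per-pixel softmax. The foreground softmax
channel is the probability map used everywhere downstream. Input sides
must be divisible by 2^depth; 448 = 512 x 0.875 supports depth <= 6.

The 2D variant consumes one slice (k = 1); the 2.5D variant consumes the
k = 3 or k = 5 adjacent slices centred on the prediction target as input
channels, giving through-plane context without 3-D convolution. At the
volume ends missing neighbours are filled by edge replication (configurable
to zero fill); replication keeps channel intensity statistics consistent at
the boundaries.

The network, its backward pass and the Adam optimiser are implemented
directly on numpy (im2col convolutions, hand-written gradients, verified
against finite differences in the test suite). Everything runs on one CPU
and is bit-deterministic for a given seed. The `encoder` field accepts
only `"simple"` (the double-conv encoder described above); a pretrained
efficientnet-style backbone is out of scope because it requires downloaded
weights.

## Loss and training

The loss is soft Dice on the foreground probabilities,

    L = 1 - (2 sum(p*t) + s) / (sum(p) + sum(t) + s),   s = 1 by default,

exposed as `dice_loss` exactly in this per-map form. Inside the training
loop the batch is scored as one pooled foreground map rather than as a mean
of per-slice losses: most axial slices contain no hematoma, and per-slice
Dice hands those slices the majority of the gradient, which reliably drags
pure-Dice training into the all-background local optimum (observed
empirically in CPU runs; the softmax gradient vanishes once the foreground
channel saturates, so the collapse is an attractor).

Defaults follow the published recipe: Adam with learning rate 1e-4 and
weight decay 1e-3 (L2 folded into the gradient), 40 epochs, per-epoch
exponential learning-rate decay with factor 0.96, augmentation probability
0.4, and an 87.5% center crop of the input slices. Two further knobs are
off by default:

* `window` — an explicit (low, high) grayscale window applied before the
  [0, 1] rescaling. The default window is each volume's own [min, max],
  which on CT-like data lets the bright skull compress the brain/collection
  contrast into a small fraction of the range; a soft-tissue window (e.g.
  (0, 100) phantom grayscale units) restores the contrast that matters.
* `empty_slice_fraction` — positive/negative slice balancing: keep at most
  this many hematoma-free slices per hematoma-bearing slice in the
  training sampling. This removes most of the all-background gradient
  pressure described above.

The 2D variant's original stopping rule ("train while the metric improves")
is implemented as optional early stopping with an explicit patience on
validation Dice; the default runs the fixed epoch count.

### Desk-scale recipe

`crescentseg.recipes` packages the configuration used by the test suite and
the acceptance script: 64x64 phantoms covering the same head geometry in mm
as the 512x512 default, 16 slices per series, a depth-2 / 8-filter U-Net,
10 epochs, learning rate 1e-3 with decay 0.85, window (0, 100), balancing
0.25, batch 8. The higher learning rate and faster decay compensate for
the short schedule; the full-scale defaults (1e-4, 0.96, 40 epochs) are
tuned for the large setting. With this recipe the 3-slice model reaches
held-out volume-level Dice around 0.85 on 20-series phantom cohorts in
roughly two minutes on one CPU core.

## Inference

For the 2D pathway a slice is predicted twice — once as-is, once left-right
mirrored — and the probability maps are averaged after mirroring back:

    tta(f, x) = ( f(x) + mirror(f(mirror(x))) ) / 2.

Averaging happens on probabilities *before* thresholding: averaging
binarized masks would make the threshold sweep ill-defined. Mirroring is
column reversal (exploiting approximate head symmetry); the axis is a
parameter. By default mirrored averaging is on for k = 1 and off for
k > 1, matching the two scenario descriptions, and both are switchable.
Predictions are made on the cropped grid and zero-padded back to the full
slice geometry so exported masks align voxel-for-voxel with the input CT.
Binarization maps a voxel exactly at the threshold to foreground (>=), for
bit-exact reproducibility.

## Evaluation

Dice 2|A∩B|/(|A|+|B|) and Jaccard |A∩B|/|A∪B| with the empty-empty
convention of 1 (no hematoma present, none predicted is a correct outcome).
Metrics are computed per series over the whole 3-D volume by default —
the stricter and better-defined aggregation — with per-slice averaging
available as an option since the original aggregation unit is unstated.

Cross-validation stratifies on the joint (embolization, hematoma count)
label. Series are sorted, shuffled within each stratum by the seed, and
dealt round-robin across folds with one continuing cursor, so fold sizes
differ by at most 1 and per-fold stratum counts deviate from exact
proportionality by less than 1. Because a patient can contribute up to
three series, folds are grouped by patient by default (greedy
smallest-fold assignment within strata) to avoid leakage; series-level
stratification (`group_by_patient=False`) gives the exactly balanced fold
sizes (seven folds of 5 and three of 6 for 53 series in 10 folds).
Fold averages are unweighted means over folds. Connected components for
per-collection volumetry use 26-connectivity in 3-D; volumes are voxel
count x voxel volume, reported in mL.

## The phantom

The generator emulates the kind of dataset the pipeline targets: series of
~60 axial 512x512 slices (desk-scale tests reduce resolution while keeping
the head's physical size), an elliptical skull ring, textured brain, and
one or two crescent-shaped hyperdense collections flush against the inner
skull table. The default 53-series cohort reproduces the reference
composition: 40 series with one hematoma, 13 with two, 26 with
embolization, 27 without, spread over 21 patients with 1-3 series each.
The joint embolization x count split (7 embolized of the 13 bilateral) and
the patient composition (12 x 3 + 8 x 2 + 1 x 1 series) are free choices
completing those marginals, which are the only published constraints.

Each crescent is an annular sector of the inner-skull ellipse in
normalized elliptic coordinates: outer boundary exactly on the inner
skull, depth following a cosine profile across the arc and a quadratic
profile through the slices. This shape was chosen over alternatives (e.g.
a difference of offset ellipses) because its per-slice area has a closed
form, so the voxel-counted mask volume can be validated against an exact
analytic volume (they agree within a few percent at 128 px, ~10x better
than the 10% test bound). Where the local depth falls below 1.25 in-plane
pixels the crescent is truncated — sub-pixel tails rasterize into
disconnected specks — and the analytic formula applies the identical
truncation.

Intensities are abstract grayscale values (air 0, brain ~40, collection
~75, skull ~230 with per-tissue smooth texture plus white noise), not
calibrated Hounsfield units: the models consume normalized grayscale, so
calibration would add nothing testable. The collection is drawn
hyperdense relative to brain, and the embolization covariate has no imaging
effect — it exists to exercise stratification.

What the phantom does *not* model: through-plane skull tapering (the head
is a cylinder), membranes/septations inside the collection, midline shift
and mass effect, beam hardening, partial-volume effects, and any
correlation between embolization status and appearance. Passing tests on
the phantom therefore demonstrate that the pipeline's machinery — data
handling, optimisation, inference, metrics, volumetry — is correct and
trainable, not that the shipped configuration reaches clinical-grade
accuracy on real CT.

## Numerical and degenerate-input choices

* Slice ordering in DICOM comes from `ImagePositionPatient` only, never
  file names; inter-slice gaps deviating more than 0.1% from their mean
  trigger a warning with the maximum deviation.
* `normalize_intensity` on a constant volume under the default window
  returns all zeros (an explicit degenerate window raises).
* Max-pooling gradient splits ties equally (deterministic on CPU).
* "Up to 87.5%" cropping is implemented as a fixed 0.875 center crop with
  `round(fraction * side)` output sides, applied uniformly to the 2D and
  2.5D pathways.
* Augmentation fires as a whole pipeline with probability p; geometric
  transforms (flip, rotation <= 15 deg, scale +-10%) are applied with
  identical parameters to every channel and to the mask
  (nearest-neighbour for masks, bilinear for images); intensity jitter
  (brightness/contrast +-20%, Gaussian noise) touches images only.
* Per-series phantom seeds derive from `SeedSequence([master_seed, index])`.
* Checkpoints store config, seed, window, crop and all weights in one
  `.npz`.

## Known limitations

Training at the full 512x512 / 40-epoch scale is CPU-bound and slow (hours);
the package is engineered for correctness and desk-scale experiments, not
throughput. The 2-fold desk-scale cross-validation trains on 8 series per
fold and shows visible fold-to-fold variance; the headline behaviour is the
held-out Dice of the 20-series smoke run. No post-processing (e.g.
largest-component filtering) is applied to predicted masks, matching the
pipeline description.
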