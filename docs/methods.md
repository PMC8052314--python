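# Methods

This note records the models, parameter choices and numerical conventions
behind the toolkit, and what its synthetic experiments do and do not show.

## Soft-mask label model

A box `(x, y, w, h)` (upper-left corner, pixel units, 0-based, half-open
pixel coverage `[x, x+w) × [y, y+h)`) is encoded as an axis-aligned
bivariate Gaussian evaluated at pixel centers `(j+½, i+½)`, mean at the box
centroid, peak value 1, zero covariance between axes. Two spread
conventions are supported:

* `std_half_extent` (default): `σ_x = w/2`, `σ_y = h/2`. The phrase
  "variance equal to half the extent" that motivates the alternative is
  dimensionally inconsistent (pixels vs pixels²), and the standard-deviation
  reading keeps the 0.6 level set near the box edge, which is what makes
  decoding work.
* `var_half_extent`: `σ_x² = w/2`, `σ_y² = h/2`, kept as a config option.

Ground-truth masks keep peak value 1 (an unnormalized kernel, not a density
integrating to 1) so they are valid binary-cross-entropy targets in [0, 1].

**Decoding.** The predicted mask is divided by its maximum, thresholded
with a strict `>` at 0.6 (configurable in (0,1)), and the tight box of the
8-connected component containing the global peak is returned (ties for the
peak break at the row-major first occurrence; the peak pixel is always
kept, so decoding never returns an empty box; an all-zero mask raises a
no-detection error). Decoding is invariant to positive rescaling. For the
default convention, the 0.6 level set of a rendered box lies at
`√(−2 ln 0.6) ≈ 1.0108` half-extents, so the decoded box is ~1% larger than
the annotation (continuous-limit IoU `1/1.0108² ≈ 0.979`); rasterization
adds up to one pixel per axis. This is why the round-trip guarantees are
stated for boxes covering ≥5% of the image *area*: below ~15 px of linear
extent the ±1 px rasterization error alone can push IoU under 0.9, which is
a property of the grid, not of the method.

## Networks and training

No GPU deep-learning stack is assumed: `ampulla.nn` is a small, fully
deterministic CNN engine on numpy (float32, NCHW) providing im2col 3×3
convolutions, 2×2 max pooling, nearest-neighbour upsampling, linear heads,
logit-space losses (stable sigmoid-BCE, softmax cross-entropy, L1 on
sigmoid) and Adam. Analytic gradients are verified against finite
differences in the test suite. All randomness (weight init, shuffling,
augmentation draws, splits) flows from explicit seeds, so same-seed runs
are bit-identical.

**Detector.** A U-Net-style encoder–decoder: `depth` conv(3×3)-ReLU stages
with 2× pooling, a bottleneck, then mirrored upsample-concat-conv stages
and a 1×1 logit head. Defaults: input 128², base 16 channels, depth 3 — but
the synthetic experiments use a smaller instance (64², base 8, depth 2)
sized to train in about a minute per run on one CPU. Loss: mean BCE against
the rendered mask of the (augmented) box. The bbox-regression baseline
shares the encoder and regresses `(x, y, w, h)/size` through a sigmoid with
mean-absolute-error loss (a robust default; the choice of regression loss
is otherwise open), with predicted extents clamped to ≥1 px.

**Classifier.** Conv-ReLU-pool stages with a flattened linear softmax head.
The flattened head (rather than global average pooling) is deliberate: some
difficulty cues are thin local structures (the crease stripe) whose signal
a global average washes out — with a pooled head the classifier collapses
to the majority class. Backbone presets (`small`, `vgg`, `resnet`,
`densenet`) select width/depth of this from-scratch CNN; no pretrained
weights are involved. Defaults: input 32², lr 1e-2, batch 32, up to 40
epochs. The higher learning rate matters: training passes through a
majority-class plateau for ~5 epochs before the minority features are
found, which also motivates the patience of 12 epochs.

**Common training protocol.** Adam, batch 16 (detector) / 32 (classifier),
an internal 80/20 train/validation split (stratified for classification),
per-iteration geometric augmentation (horizontal/vertical flips p=0.5,
rotation ±15°, shear ±10°, identical transform applied to image and label;
box labels become the clipped tight box of the transformed corners, and a
transform that expels the whole box is re-drawn, falling back to identity
after 10 attempts). Early stopping keeps the weights of the best validation
epoch: success rate at IoU 0.3 for detection (the "usefully localized"
threshold; the detection selection metric is an implementation choice),
macro-F1 or accuracy for classification (both offered, since which of the
two drives early stopping changes which model variant you get). Optimizer, batch size and patience are toolkit defaults, not claims
about the original experiment.

## Difficulty labels

`map_outcome` is total and deterministic over valid records: failure (not
`success`) → `failure` regardless of other fields; else additional
technique → `additional_technique`; else time > 300 s (strictly) →
`over_5min`; else `easy`. Precedence of technique over time follows the
reported class structure, where every additional-technique case also ran
over five minutes, so the two only overlap in that direction. Binary
difficult ≡ four-class ≠ easy, structurally. Negative times and successful
cases without a time are rejected. Binary AUC ranks the predicted
probability of the difficult class; multiclass AUC is not produced. No
class re-weighting is applied by default (the class imbalance is part of
the modelled conditions).

## Synthetic data generator

Each scene holds exactly one target: a bright ellipse with
`sqrt(1 − r²)` radial falloff and smooth multiplicative texture on a darker
background with low-contrast distractor ellipses and smooth noise; images
get a reddish mucosa-like tint. The ground-truth box is the tight box of
the support ellipse. Class-conditional features echo qualitative cues from
real imagery: `over_5min` scenes get a small target and doubled clutter,
`additional_technique` a dark crease stripe across the upper target,
`failure` minimal target contrast and tripled clutter.
`difficulty_feature_strength` in [0, 1] is the probability that the visual
features match the label (lower values substitute a random class's
features — label noise). Outcome records are sampled so the label rules
reproduce the intended class exactly: easy times U(30, 300) s, over-5-min
and technique times U(301, 1200) s, failures with no recorded time.

Defaults: target scale 0.1–0.4 of the image extent, aspect 0.5–2, five
distractors, texture sd 10 gray levels, class mix 68 / 13 / 18 / 1 %
(matching the outcome distribution of a large ERCP series in which about a
third of cannulations are difficult). The interior-vs-background contrast
margin (default 40 gray levels, measured on the channel mean) is enforced
per sample: if clutter erodes it, the target is topped up — this is the
generator's learnability contract.

What passing on this generator shows: the pipeline's machinery (label
encoding, training, decoding, metrics, CV protocol) is correct and the
ordering soft-mask > bbox-regression is reproducible under controlled
conditions. What it does not show: performance on real endoscopic images,
whose texture, lighting, anatomy (diverticula) and annotation ambiguity the
generator does not model. The feature→difficulty links are constructions,
not claims about anatomy. With ~1% prevalence the failure class is
essentially unlearnable at n = 600 (a handful of examples); four-class
macro-recall is carried by the other three classes, mirroring the real
difficulty of rare-class recognition.

## Problem sizes and numerical choices

* Synthetic benchmark: 600 train / 200 test images at 64×64, detector
  (base 8, depth 2, ≤8 epochs, patience 3), averaged over 5 training seeds
  in the test suite and 3 in the acceptance script — sizes chosen so the
  whole suite runs in minutes on a single CPU while leaving the qualitative
  ordering stable across seeds.
* Classifier recovery: 600 images at 32×32, fully informative features,
  stratified 75/25 split, 3 training seeds. The binary task uses the
  `small` preset (8 base channels); the four-class task uses the wider
  `resnet` preset (16 base channels) — separating the three difficult
  subclasses rides on finer cues than the binary split and the narrow net
  plateaus below them regardless of training length.
* BCE clipping ε = 1e-7; mask PNG export quantizes to 8 bits (NPZ is the
  lossless, authoritative format); aggregation uses the population standard
  deviation (ddof = 0) across images/folds; success-curve comparisons are
  strict (`>` for IoU, `<` for centroid distance).
* Detection "precision/recall" are per-image area-overlap ratios, the
  natural reading when reported alongside a per-image IoU; they are not
  dataset-level classification counts.

## Known limitations

* Single-object assumption throughout (one ampulla per image): no
  multi-instance decoding, confidence scores or mAP.
* Gaussians are axis-aligned; oriented/rotated covariance is out of scope.
* The CNN engine favours determinism and simplicity over speed; it is not
  meant for large-scale training, and no pretrained backbones are
  available.
* Checkpoints store raw float32 weights with the config; they are not
  portable across architecture-config changes.
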