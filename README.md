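# ampulla

Single-object detection and difficulty classification for ERCP endoscopy
images: locate the ampulla of Vater (AOV) in a duodenal view and predict,
from the image alone, how difficult selective biliary cannulation will be.

During endoscopic retrograde cholangiopancreatography (ERCP) the
endoscopist must find the ampulla — the papilla where the bile and
pancreatic ducts open into the duodenum — and cannulate the common bile
duct through it. The ampulla has no crisp boundary: it blends gradually
into the surrounding mucosa, which makes strict bounding-box regression an
awkward fit. This toolkit implements the soft-mask alternative and
everything needed to train and evaluate it, for researchers who want to
reproduce, extend or stress-test the approach without access to patient
data.

## The method

**Soft-mask labels.** A bounding-box annotation `(x, y, w, h)` is converted
into a per-pixel probability map: an axis-aligned bivariate Gaussian with
mean at the box centroid `μ = (x + w/2, y + h/2)`, spreads tied to the box
extents (default `σ_x = w/2`, `σ_y = h/2`), and peak value 1,

    m(i, j) = exp(−½ [((j+½−μ_x)/σ_x)² + ((i+½−μ_y)/σ_y)²]).

A small U-Net-style encoder–decoder is trained against these masks with
mean binary cross-entropy. At inference the predicted mask is normalized to
peak 1, thresholded at 0.6, and the tight box of the connected component
containing the peak is returned. In the continuous limit the 0.6 level set
sits at `√(−2 ln 0.6) ≈ 1.0108` half-extents, so decode(render(box))
recovers the annotation to ~1%. A direct bbox-regression baseline (same
encoder, 4-way coordinate head, MAE loss) is included for comparison.

**Detection metrics.** Per image: IoU, area precision `|pred∩gt|/|pred|`,
area recall `|pred∩gt|/|gt|`, and the relative centroid distance

    d = ½ (|x_g − x_e| / W + |y_g − y_e| / H),

plus success plots (fraction of images whose IoU exceeds / centroid
distance falls below a threshold sweep) and three-way annotator-agreement
comparisons.

**Difficulty labels and classifiers.** Procedural outcomes map to labels
with precedence failure > additional technique > over-5-minutes > easy
(binary: easy vs difficult = not easy). A small CNN classifier predicts the
label from the image; evaluation reports per-class precision/recall/F1,
accuracy, binary AUC and macro averages under stratified five-fold
cross-validation (mean ± sd over folds).

**Synthetic data.** Patient images cannot be shared, so a seeded generator
produces endoscopy-like scenes: one bright ellipse with radial falloff and
multiplicative texture on a cluttered background, with the ground-truth box,
a difficulty label tied to latent visual features (size, clutter, a crease
stripe, contrast) and a consistent outcome record.

## Worked example

```bash
python examples/01_render_and_decode.py
```

prints

```
original box : (40.5, 30.25, 37.0, 27.5)
decoded box  : (40.0, 30.0, 38.0, 28.0)
IoU          : 0.9563
centroid dist: 0.0000
width ratio  : 1.0270  (continuous limit 1.0108)
```

— the decoded box is one pixel wider per axis than the annotation, exactly
the ~1% level-set inflation plus rasterization, with the centroid recovered
essentially perfectly. The other examples train the detector pair
(`03_train_detector.py`; on its 320/80 split the soft-mask model reaches
mIoU 0.68 and 100% success at IoU 0.3 while the regression baseline
manages 15%),
train a difficulty classifier (`04_difficulty_classification.py`; held-out
binary accuracy 0.92, macro-F1 0.90 on its small run), score
annotation sets against each other (`02_detection_metrics.py`) and write /
re-read fixture directories (`05_synthetic_fixtures.py`).

A thin CLI mirrors the library for shell use:

```bash
ampulla simulate --n-images 100 --seed 0 --out fixtures/
ampulla render --annotations fixtures/annotations.json --out masks/
ampulla decode --masks masks/ --threshold 0.6 --out boxes.json
ampulla train-detect --data fixtures/ --out run/
ampulla eval-classify --task binary --out reports/
```

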