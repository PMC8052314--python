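"""Score one annotation set against another and build a success plot.

Treats set A as ground truth and set B as the estimate (the same machinery
scores a model against an expert, or two annotators against each other) and
prints the mean +/- sd of each per-image metric, then the fraction of images
whose IoU clears each threshold.
"""

from ampulla import BBox, compare_annotations, success_curve

set_a = [BBox(30, 30, 20, 20), BBox(50, 40, 30, 24), BBox(10, 60, 24, 30)]
set_b = [BBox(32, 31, 20, 20), BBox(48, 42, 28, 22), BBox(12, 58, 22, 32)]

summary = compare_annotations(set_a, set_b, image_sizes=(128, 128))
print(f"mIoU              : {summary.mean.iou:.3f} +/- {summary.sd.iou:.3f}")
print(f"area precision    : {summary.mean.area_precision:.3f}")
print(f"area recall       : {summary.mean.area_recall:.3f}")
print(f"centroid distance : {summary.mean.centroid_distance:.4f}")

curve = success_curve(summary.evals, "iou")
for t, r in zip(curve.thresholds, curve.rates):
    print(f"  success rate @ IoU > {t:.1f}: {100 * r:.0f}%")
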