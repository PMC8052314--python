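"""Train the soft-mask U-Net and the bbox-regression baseline on a small
synthetic dataset and compare them.

The soft-mask route (predict a per-pixel Gaussian heatmap, decode the box
from its 0.6 level set) consistently beats direct coordinate regression on
the success rate at IoU 0.3.  Takes a couple of minutes on one CPU.
"""

import numpy as np

from ampulla import DetectorConfig, SynthConfig, generate_dataset
from ampulla.detector import train_soft_mask_detector, train_bbox_regressor
from ampulla.experiments import evaluate_detector

samples = generate_dataset(SynthConfig(n_images=400, image_size=64, seed=42))
train = [(s.image, s.gt_box) for s in samples[:320]]
test = samples[320:]

config = DetectorConfig(input_size=64, base_channels=8, depth=2,
                        max_epochs=10, early_stop_patience=4, seed=0)

for name, trainer in [("soft-mask U-Net", train_soft_mask_detector),
                      ("bbox regressor ", train_bbox_regressor)]:
    model = trainer(train, config)
    evals = evaluate_detector(model, test)
    miou = np.mean([e.iou for e in evals])
    succ = np.mean([e.iou > 0.3 for e in evals])
    cd = np.mean([e.centroid_distance for e in evals])
    print(f"{name}: mIoU {miou:.3f}  success@IoU0.3 {100 * succ:.0f}%  centroid dist {cd:.3f}")
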