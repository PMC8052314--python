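"""Trainable single-object detectors: soft-mask U-Net and bbox-regression baseline.

Two models share the same small convolutional encoder:

* :func:`train_soft_mask_detector` — a U-Net-style encoder/decoder that
  predicts a per-pixel soft mask (sigmoid logits trained with binary
  cross-entropy against rendered Gaussian labels).  At prediction time the
  mask is decoded back to a box by the peak-threshold rule.
* :func:`train_bbox_regressor` — the baseline that regresses the four box
  coordinates directly (normalized to [0, 1] by image size, mean absolute
  error loss).

Both are deliberately small, from-scratch networks sized to train on a
single CPU in minutes; width and depth are configurable for larger budgets.
Model selection uses the validation success rate at IoU 0.3 with early
stopping.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import warp as _sk_warp

from . import nn
from .geometry import BBox, iou
from .softlabel import DecodeSpec, GaussianLabelSpec, decode_mask_to_bbox, render_soft_mask

__all__ = [
    "DetectorConfig",
    "TrainedDetector",
    "DegenerateAugmentationError",
    "augment_pair",
    "sample_ops",
    "train_soft_mask_detector",
    "train_bbox_regressor",
    "predict_box",
    "predict_box_regressor",
    "save_checkpoint",
    "load_checkpoint",
]


class DegenerateAugmentationError(ValueError):
    """A geometric transform pushed the whole box outside the image."""


@dataclass
class DetectorConfig:
    """Training configuration shared by the soft-mask model and the baseline.

    ``augmentation`` names the geometric ops sampled each iteration
    (subset of hflip / vflip / shear / rotate); ``rotate_range`` and
    ``shear_range`` are the half-widths of the uniform angle draws in
    degrees, ``flip_p`` the per-flip probability.
    """

    input_size: int = 128
    base_channels: int = 16
    depth: int = 3
    learning_rate: float = 3e-3
    max_epochs: int = 30
    early_stop_patience: int = 10
    batch_size: int = 16
    val_fraction: float = 0.2
    seed: int = 0
    augmentation: tuple[str, ...] = ("hflip", "vflip", "shear", "rotate")
    rotate_range: float = 15.0
    shear_range: float = 10.0
    flip_p: float = 0.5
    sigma_mode: str = "std_half_extent"
    decode_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )
        bad = set(self.augmentation) - {"hflip", "vflip", "shear", "rotate"}
        if bad:
            raise ValueError(f"unknown augmentation ops: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Geometric augmentation applied identically to image and label
# ---------------------------------------------------------------------------


def _affine_matrix(op: str, param: float, w: int, h: int) -> np.ndarray:
    """Forward 3x3 transform in continuous pixel coordinates (origin at the
    image corner, pixel centers at half-integers), acting about the center."""
    cx, cy = w / 2.0, h / 2.0
    t_in = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    t_out = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    if op == "rotate":
        a = np.deg2rad(param)
        m = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    elif op == "shear":
        m = np.array([[1, np.tan(np.deg2rad(param)), 0], [0, 1, 0], [0, 0, 1]])
    else:  # pragma: no cover - guarded by caller
        raise ValueError(op)
    return t_out @ m @ t_in


def _warp_image(image: np.ndarray, fwd: np.ndarray) -> np.ndarray:
    # skimage uses (row, col) with pixel centers at integers; our continuous
    # coords are (col + 1/2, row + 1/2).  Conjugate by the half-pixel shift.
    shift = np.array([[1, 0, 0.5], [0, 1, 0.5], [0, 0, 1]], dtype=float)
    fwd_sk = np.linalg.inv(shift) @ fwd @ shift
    inv = np.linalg.inv(fwd_sk)

    def inverse_map(coords: np.ndarray) -> np.ndarray:
        # coords: (M, 2) as (col, row) in output image
        pts = np.column_stack([coords, np.ones(len(coords))])
        src = pts @ inv.T
        return src[:, :2]

    return _sk_warp(image, inverse_map, order=1, mode="constant", cval=0.0, preserve_range=True)


def _transform_box(box: BBox, fwd: np.ndarray, w: int, h: int) -> BBox:
    corners = np.array(
        [[box.x, box.y, 1], [box.x2, box.y, 1], [box.x, box.y2, 1], [box.x2, box.y2, 1]],
        dtype=float,
    )
    out = corners @ fwd.T
    x1, y1 = out[:, 0].min(), out[:, 1].min()
    x2, y2 = out[:, 0].max(), out[:, 1].max()
    if x2 <= 0 or y2 <= 0 or x1 >= w or y1 >= h:
        raise DegenerateAugmentationError("transformed box lies entirely outside the image")
    return BBox(x1, y1, x2 - x1, y2 - y1).clip(w, h)


def augment_pair(
    image: np.ndarray,
    box_or_mask: BBox | np.ndarray,
    ops: Sequence[str | tuple[str, float]],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, BBox | np.ndarray]:
    """Apply the same geometric ops to an image and its label.

    ``ops`` is an ordered list of concrete operations: ``"hflip"``,
    ``"vflip"``, ``("rotate", degrees)`` or ``("shear", degrees)``.  Bare
    ``"rotate"``/``"shear"`` draw their angle uniformly from ±15° / ±10°
    using ``rng``.  A box label is transformed as the tight axis-aligned box
    of its transformed corners, clipped to the image; a mask label is warped
    with the identical transform.  An op list that pushes the whole box
    outside the image raises :class:`DegenerateAugmentationError`.
    """
    h, w = image.shape[:2]
    img = np.asarray(image)
    label = box_or_mask
    for op in ops:
        if isinstance(op, tuple):
            name, param = op
        else:
            name, param = op, None
        if name == "hflip":
            img = img[:, ::-1].copy()
            if isinstance(label, BBox):
                label = BBox(w - label.x - label.w, label.y, label.w, label.h)
            else:
                label = label[:, ::-1].copy()
        elif name == "vflip":
            img = img[::-1].copy()
            if isinstance(label, BBox):
                label = BBox(label.x, h - label.y - label.h, label.w, label.h)
            else:
                label = label[::-1].copy()
        elif name in ("rotate", "shear"):
            if param is None:
                if rng is None:
                    raise ValueError(f"{name} without an angle requires an rng")
                rng_range = 15.0 if name == "rotate" else 10.0
                param = float(rng.uniform(-rng_range, rng_range))
            fwd = _affine_matrix(name, param, w, h)
            img = _warp_image(img, fwd)
            if isinstance(label, BBox):
                label = _transform_box(label, fwd, w, h)
            else:
                label = _warp_image(label, fwd)
        else:
            raise ValueError(f"unknown augmentation op {name!r}")
    return img, label


def sample_ops(config: DetectorConfig, rng: np.random.Generator) -> list[str | tuple[str, float]]:
    """Draw one random op list according to the configured augmentation set."""
    ops: list[str | tuple[str, float]] = []
    for name in config.augmentation:
        if name in ("hflip", "vflip"):
            if rng.random() < config.flip_p:
                ops.append(name)
        elif name == "rotate":
            ops.append(("rotate", float(rng.uniform(-config.rotate_range, config.rotate_range))))
        elif name == "shear":
            ops.append(("shear", float(rng.uniform(-config.shear_range, config.shear_range))))
    return ops


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class _Encoder:
    """Conv-ReLU stages with 2x2 max pooling between them."""

    def __init__(self, in_ch: int, base: int, depth: int, rng: np.random.Generator) -> None:
        self.blocks: list[nn.Sequential] = []
        self.pools: list[nn.MaxPool2d] = []
        ch = in_ch
        for d in range(depth):
            out = base * 2**d
            self.blocks.append(nn.Sequential(nn.Conv2d(ch, out, rng=rng), nn.ReLU()))
            self.pools.append(nn.MaxPool2d())
            ch = out
        self.bottleneck = nn.Sequential(nn.Conv2d(ch, ch * 2, rng=rng), nn.ReLU())
        self.out_ch = ch * 2

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        skips = []
        for block, pool in zip(self.blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        return self.bottleneck.forward(x), skips

    def backward(self, dy: np.ndarray, dskips: list[np.ndarray] | None) -> np.ndarray:
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(len(self.blocks))):
            dy = self.pools[i].backward(dy)
            if dskips is not None:
                dy = dy + dskips[i]
            dy = self.blocks[i].backward(dy)
        return dy

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for b in self.blocks:
            out.extend(b.iter_layers())
        out.extend(self.bottleneck.iter_layers())
        return out


class UNet:
    """Encoder-decoder with skip connections and a 1-channel logit head."""

    def __init__(self, in_ch: int = 3, base: int = 16, depth: int = 3, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.encoder = _Encoder(in_ch, base, depth, rng)
        self.ups = [nn.UpsampleNearest2d() for _ in range(depth)]
        self.dec_blocks: list[nn.Sequential] = []
        ch = self.encoder.out_ch
        for d in reversed(range(depth)):
            skip_ch = base * 2**d
            self.dec_blocks.append(
                nn.Sequential(nn.Conv2d(ch + skip_ch, skip_ch, rng=rng), nn.ReLU())
            )
            ch = skip_ch
        self.head = nn.Conv2d(ch, 1, kernel=1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, skips = self.encoder.forward(x)
        self._split = []
        for i, block in enumerate(self.dec_blocks):
            y = self.ups[i].forward(y)
            skip = skips[self.depth - 1 - i]
            self._split.append(y.shape[1])
            y = np.concatenate([y, skip], axis=1)
            y = block.forward(y)
        return self.head.forward(y)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(dy)
        dskips: list[np.ndarray | None] = [None] * self.depth
        for i in reversed(range(len(self.dec_blocks))):
            dcat = self.dec_blocks[i].backward(dy)
            up_ch = self._split[i]
            dskips[self.depth - 1 - i] = dcat[:, up_ch:]
            dy = self.ups[i].backward(dcat[:, :up_ch])
        self.encoder.backward(dy, dskips)  # type: ignore[arg-type]

    def layers(self) -> list[nn.Layer]:
        out = self.encoder.layers()
        for b in self.dec_blocks:
            out.extend(b.iter_layers())
        out.append(self.head)
        return out


class BBoxRegressorNet:
    """Same encoder, global-average-pooled into a 4-way sigmoid head."""

    def __init__(self, in_ch: int = 3, base: int = 16, depth: int = 3, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(in_ch, base, depth, rng)
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(self.encoder.out_ch, 4, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.encoder.forward(x)
        return self.fc.forward(self.pool.forward(y))

    def backward(self, dy: np.ndarray) -> None:
        self.encoder.backward(self.pool.backward(self.fc.backward(dy)), None)

    def layers(self) -> list[nn.Layer]:
        return self.encoder.layers() + [self.fc]


@dataclass
class TrainedDetector:
    """A trained model plus its configuration and per-epoch training log."""

    model: object
    config: DetectorConfig
    training_log: list[dict]
    kind: str  # "soft_mask" or "bbox_regressor"
    best_epoch: int = 0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _prepare(dataset: Sequence[tuple[np.ndarray, BBox]], size: int) -> tuple[np.ndarray, list[BBox]]:
    """Resize images to the model input size, scale boxes accordingly,
    normalize intensities to [0, 1], channels-first."""
    images = np.empty((len(dataset), 3, size, size), dtype=np.float32)
    boxes: list[BBox] = []
    for i, (img, box) in enumerate(dataset):
        arr = np.asarray(img, dtype=np.float32)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        h, w = arr.shape[:2]
        if (h, w) != (size, size):
            arr = _sk_resize(arr, (size, size), order=1, preserve_range=True, anti_aliasing=False)
        images[i] = (arr / 255.0).transpose(2, 0, 1)
        boxes.append(
            BBox(box.x * size / w, box.y * size / h, box.w * size / w, box.h * size / h)
        )
    return images, boxes


def _state_dict(model) -> list[dict[str, np.ndarray]]:
    return [copy.deepcopy(l.params) for l in model.layers()]


def _load_state(model, state: list[dict[str, np.ndarray]]) -> None:
    for layer, params in zip(model.layers(), state):
        for k in layer.params:
            layer.params[k][...] = params[k]


def _success_at_iou(gt: Sequence[BBox], pred: Sequence[BBox], thr: float = 0.3) -> float:
    return float(np.mean([iou(g, p) > thr for g, p in zip(gt, pred)]))


def _augmented_batch(
    images: np.ndarray,
    boxes: list[BBox],
    idx: np.ndarray,
    config: DetectorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[BBox]]:
    out_imgs = np.empty((len(idx),) + images.shape[1:], dtype=np.float32)
    out_boxes: list[BBox] = []
    for j, i in enumerate(idx):
        img = images[i].transpose(1, 2, 0)
        for _ in range(10):  # re-draw on degenerate transforms
            ops = sample_ops(config, rng)
            try:
                aimg, abox = augment_pair(img, boxes[i], ops, rng)
                break
            except DegenerateAugmentationError:
                continue
        else:
            aimg, abox = img, boxes[i]
        out_imgs[j] = np.asarray(aimg, dtype=np.float32).transpose(2, 0, 1)
        out_boxes.append(abox)  # type: ignore[arg-type]
    return out_imgs, out_boxes


def _split_train_val(n: int, val_fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    return order[n_val:], order[:n_val]


def _train_loop(
    model,
    images: np.ndarray,
    boxes: list[BBox],
    config: DetectorConfig,
    step_fn: Callable[[np.ndarray, list[BBox]], float],
    val_fn: Callable[[np.ndarray, list[BBox]], float],
) -> list[dict]:
    """Shared epoch loop with early stopping on the validation success rate."""
    rng = np.random.default_rng(config.seed)
    tr, va = _split_train_val(len(boxes), config.val_fraction, rng)
    val_imgs = images[va]
    val_boxes = [boxes[i] for i in va]
    log: list[dict] = []
    best_metric, best_state, best_epoch, since_best = -np.inf, None, 0, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            bimgs, bboxes = _augmented_batch(images, boxes, idx, config, rng)
            losses.append(step_fn(bimgs, bboxes))
        val_metric = val_fn(val_imgs, val_boxes)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_success_iou03": val_metric}
        )
        if val_metric > best_metric:
            best_metric, best_state, best_epoch, since_best = val_metric, _state_dict(model), epoch, 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    if best_state is not None:
        _load_state(model, best_state)
    return log, best_epoch


def train_soft_mask_detector(
    dataset: Sequence[tuple[np.ndarray, BBox]],
    config: DetectorConfig | None = None,
) -> TrainedDetector:
    """Train the U-Net soft-mask detector on (image, box) pairs.

    Targets are Gaussian soft masks rendered from the (augmented) boxes; the
    loss is mean binary cross-entropy on the sigmoid logits.  The returned
    detector carries the weights of the epoch with the best validation
    success rate at IoU 0.3.
    """
    config = config or DetectorConfig()
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    size = config.input_size
    images, boxes = _prepare(dataset, size)
    model = UNet(base=config.base_channels, depth=config.depth, seed=config.seed)
    opt = nn.Adam(model.layers(), lr=config.learning_rate)
    label_spec = GaussianLabelSpec(config.sigma_mode)
    decode_spec = DecodeSpec(config.decode_threshold)

    def render_targets(bs: list[BBox]) -> np.ndarray:
        t = np.empty((len(bs), 1, size, size), dtype=np.float32)
        for i, b in enumerate(bs):
            t[i, 0] = render_soft_mask(b.clip(size, size), size, size, label_spec)
        return t

    def step(bimgs: np.ndarray, bboxes: list[BBox]) -> float:
        logits = model.forward(bimgs)
        loss, grad = nn.bce_with_logits(logits, render_targets(bboxes))
        model.backward(grad)
        opt.step()
        return loss

    def validate(vimgs: np.ndarray, vboxes: list[BBox]) -> float:
        preds = []
        for start in range(0, len(vimgs), config.batch_size):
            logits = model.forward(vimgs[start : start + config.batch_size])
            for m in nn.sigmoid(logits)[:, 0]:
                preds.append(decode_mask_to_bbox(m, decode_spec))
        return _success_at_iou(vboxes, preds)

    log, best_epoch = _train_loop(model, images, boxes, config, step, validate)
    return TrainedDetector(
        model=model, config=config, training_log=log, kind="soft_mask", best_epoch=best_epoch
    )


def train_bbox_regressor(
    dataset: Sequence[tuple[np.ndarray, BBox]],
    config: DetectorConfig | None = None,
) -> TrainedDetector:
    """Train the direct bbox-regression baseline (MAE on normalized x,y,w,h)."""
    config = config or DetectorConfig()
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    size = config.input_size
    images, boxes = _prepare(dataset, size)
    model = BBoxRegressorNet(base=config.base_channels, depth=config.depth, seed=config.seed)
    opt = nn.Adam(model.layers(), lr=config.learning_rate)

    def targets(bs: list[BBox]) -> np.ndarray:
        return np.array([[b.x / size, b.y / size, b.w / size, b.h / size] for b in bs], dtype=np.float32)

    def step(bimgs: np.ndarray, bboxes: list[BBox]) -> float:
        logits = model.forward(bimgs)
        loss, grad = nn.l1_on_sigmoid(logits, targets(bboxes))
        model.backward(grad)
        opt.step()
        return loss

    def validate(vimgs: np.ndarray, vboxes: list[BBox]) -> float:
        preds = []
        for start in range(0, len(vimgs), config.batch_size):
            logits = model.forward(vimgs[start : start + config.batch_size])
            for row in nn.sigmoid(logits):
                preds.append(_denorm_box(row, size))
        return _success_at_iou(vboxes, preds)

    log, best_epoch = _train_loop(model, images, boxes, config, step, validate)
    return TrainedDetector(
        model=model, config=config, training_log=log, kind="bbox_regressor", best_epoch=best_epoch
    )


def _denorm_box(row: np.ndarray, size: int) -> BBox:
    x, y, w, h = (float(v) * size for v in row)
    w = max(w, 1.0)  # predicted extents clamped to at least one pixel
    h = max(h, 1.0)
    return BBox(x, y, w, h).clip(size, size)


def predict_box(model: TrainedDetector, image: np.ndarray) -> tuple[np.ndarray, BBox]:
    """Predict the soft mask and decoded box for one image.

    The mask is resized back to the original image resolution before
    decoding, so ``decode_mask_to_bbox`` applied to the returned mask yields
    exactly the returned box.
    """
    h, w = np.asarray(image).shape[:2]
    size = model.config.input_size
    imgs, _ = _prepare([(image, BBox(0, 0, w, h))], size)
    if model.kind == "bbox_regressor":
        return predict_box_regressor(model, image)
    logits = model.model.forward(imgs)
    mask = nn.sigmoid(logits)[0, 0].astype(np.float64)
    if (h, w) != (size, size):
        mask = _sk_resize(mask, (h, w), order=1, preserve_range=True)
    box = decode_mask_to_bbox(mask, DecodeSpec(model.config.decode_threshold))
    return mask, box.clip(w, h)


def predict_box_regressor(model: TrainedDetector, image: np.ndarray) -> tuple[np.ndarray, BBox]:
    """Baseline prediction; the 'mask' is the rendered Gaussian of the box."""
    h, w = np.asarray(image).shape[:2]
    size = model.config.input_size
    imgs, _ = _prepare([(image, BBox(0, 0, w, h))], size)
    row = nn.sigmoid(model.model.forward(imgs))[0]
    box = _denorm_box(row, size)
    box = BBox(box.x * w / size, box.y * h / size, box.w * w / size, box.h * h / size).clip(w, h)
    mask = render_soft_mask(box, h, w, GaussianLabelSpec(model.config.sigma_mode))
    return mask, box


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(detector: TrainedDetector, path: str) -> None:
    """Save weights + config + training log in one .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(detector.model.layers()):
        for k, v in layer.params.items():
            arrays[f"layer{i}.{k}"] = v
    meta = json.dumps(
        {"config": asdict(detector.config), "training_log": detector.training_log, "kind": detector.kind}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> TrainedDetector:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["augmentation"] = tuple(cfg_dict["augmentation"])
    config = DetectorConfig(**cfg_dict)
    if meta["kind"] == "soft_mask":
        model = UNet(base=config.base_channels, depth=config.depth, seed=config.seed)
    else:
        model = BBoxRegressorNet(base=config.base_channels, depth=config.depth, seed=config.seed)
    for i, layer in enumerate(model.layers()):
        for k in layer.params:
            layer.params[k][...] = data[f"layer{i}.{k}"]
    return TrainedDetector(model=model, config=config, training_log=meta["training_log"], kind=meta["kind"])
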