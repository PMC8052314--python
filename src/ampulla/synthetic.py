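"""Seeded generator of endoscopy-like images with boxes and outcome records.

Real ERCP images of the ampulla of Vater cannot be shared, so every other
module is exercised on synthetic scenes that reproduce the *structure* of
the task: each image contains exactly one salient bright ellipse ("the
ampulla") with radial falloff and multiplicative texture, on a darker
cluttered background of low-contrast distractor blobs.  The ground-truth box
is the tight box of the ellipse's support.

Difficulty labels are tied to latent visual features, loosely echoing the
qualitative cues reported for real images:

* ``easy`` — large, bright, low clutter;
* ``over_5min`` — small target with heavy background clutter;
* ``additional_technique`` — a dark crease stripe across the upper target;
* ``failure`` — minimal target contrast and maximal clutter.

``difficulty_feature_strength`` in [0, 1] controls how reliably the visual
features follow the label (1 = fully informative; lower values swap in the
features of a random class with probability ``1 - strength``).  Outcome
records are sampled so that mapping them back through the label rules
reproduces the intended class (easy times U(30, 300) s, over-5-minute times
U(301, 1200) s, failures carry no time).

The default class mix (68 / 13 / 18 / 1 %) mirrors the outcome distribution
typical of large ERCP series, where roughly a third of cannulations are
difficult.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .difficulty import DifficultyLabel, OutcomeRecord, map_outcome, FOUR_CLASSES
from .geometry import BBox
from . import io as ampio

__all__ = ["SynthConfig", "SynthSample", "GenerationError", "generate_dataset", "write_fixture", "read_fixture"]


class GenerationError(RuntimeError):
    """Sample geometry could not be placed after bounded retries."""


@dataclass
class SynthConfig:
    n_images: int = 100
    image_size: int = 64
    blob_scale_range: tuple[float, float] = (0.1, 0.4)  # fraction of image extent
    aspect_range: tuple[float, float] = (0.5, 2.0)
    texture_noise_sd: float = 10.0  # gray levels
    n_distractors: int = 5
    difficulty_feature_strength: float = 1.0
    class_mix: tuple[float, float, float, float] = (0.68, 0.13, 0.18, 0.01)
    contrast_margin: float = 40.0  # gray levels between blob interior and background means
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not (0.0 <= self.difficulty_feature_strength <= 1.0):
            raise ValueError("difficulty_feature_strength must lie in [0, 1]")
        if self.blob_scale_range[1] >= 0.95:
            raise ValueError("largest blob scale must leave room inside the image")


@dataclass
class SynthSample:
    image: np.ndarray  # (H, W, 3) uint8
    gt_box: BBox
    outcome: OutcomeRecord
    label: DifficultyLabel
    latent: dict


def _sample_geometry(cfg: SynthConfig, visual: str, rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Ellipse center and semi-axes (cx, cy, a, b), guaranteed inside."""
    size = cfg.image_size
    lo, hi = cfg.blob_scale_range
    if visual == "over_5min":  # small target
        scale = rng.uniform(lo, lo + 0.3 * (hi - lo))
    elif visual == "easy":  # comfortably large target
        scale = rng.uniform(lo + 0.4 * (hi - lo), hi)
    else:
        scale = rng.uniform(lo, hi)
    aspect = rng.uniform(*cfg.aspect_range)
    a = 0.5 * scale * size * np.sqrt(aspect)
    b = 0.5 * scale * size / np.sqrt(aspect)
    a = float(np.clip(a, 1.5, size / 2 - 2))  # lower bound keeps pixels inside
    b = float(np.clip(b, 1.5, size / 2 - 2))
    for _ in range(100):
        cx = rng.uniform(a + 1, size - a - 1)
        cy = rng.uniform(b + 1, size - b - 1)
        return cx, cy, a, b
    raise GenerationError("could not place the target ellipse")


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _render_scene(cfg: SynthConfig, visual: str, rng: np.random.Generator) -> tuple[np.ndarray, BBox, dict]:
    size = cfg.image_size
    cx, cy, a, b = _sample_geometry(cfg, visual, rng)

    base = rng.uniform(55, 75)
    img = base + 12.0 * _smooth_noise((size, size), rng, sigma=size / 10)

    n_clutter = cfg.n_distractors
    if visual == "over_5min":
        n_clutter *= 2
    elif visual == "failure":
        n_clutter *= 3
    ys, xs = np.mgrid[0:size, 0:size]
    pxs, pys = xs + 0.5, ys + 0.5
    for _ in range(n_clutter):
        dcx, dcy = rng.uniform(0, size, 2)
        da, db = rng.uniform(0.04, 0.12, 2) * size + 1.5
        r2 = ((pxs - dcx) / da) ** 2 + ((pys - dcy) / db) ** 2
        img += rng.uniform(10, 25) * np.clip(1 - r2, 0, None)

    # Target: amplitude 1.5x the wanted margin, since the mean of
    # sqrt(1 - r^2) over the unit disk is 2/3.
    extra = 0.0 if visual == "failure" else rng.uniform(10, 45)
    amplitude = 1.5 * (cfg.contrast_margin + extra)
    r2 = ((pxs - cx) / a) ** 2 + ((pys - cy) / b) ** 2
    falloff = np.sqrt(np.clip(1.0 - r2, 0.0, None))
    texture = 1.0 + (cfg.texture_noise_sd / max(amplitude, 1.0)) * _smooth_noise(
        (size, size), rng, sigma=1.5
    )
    blob = amplitude * falloff * np.clip(texture, 0.4, 1.6)

    crease = visual == "additional_technique"
    if crease:
        # dark stripe across the upper half of the target
        stripe = np.abs(pys - (cy - 0.45 * b)) < max(b / 5.0, 1.5)
        blob = np.where(stripe & (r2 < 1), blob * 0.25, blob)

    img = img + blob
    tint = np.array([1.0, 0.82, 0.72])  # duodenal mucosa is reddish
    # enforce the learnability contract: the blob interior must outshine the
    # background mean by at least contrast_margin gray levels (measured on
    # the channel mean of the final image), whatever the clutter drew
    inside = r2 < 1.0
    if not inside.any() or inside.all():
        raise GenerationError("degenerate target support")
    measured = (img[inside].mean() - img[~inside].mean()) * tint.mean()
    wanted = cfg.contrast_margin + 2.0
    if measured < wanted:
        img = img + (wanted - measured) / (falloff[inside].mean() * tint.mean()) * falloff
    rgb = img[:, :, None] * tint[None, None, :]
    rgb += rng.normal(0, 2.0, rgb.shape)
    image = np.clip(rgb, 0, 255).astype(np.uint8)

    box = BBox(cx - a, cy - b, 2 * a, 2 * b)
    latent = {
        "center": (cx, cy),
        "axes": (a, b),
        "visual_class": visual,
        "crease": crease,
        "amplitude": amplitude,
        "n_clutter": n_clutter,
    }
    return image, box, latent


def _sample_outcome(label: str, rng: np.random.Generator) -> OutcomeRecord:
    if label == "easy":
        return OutcomeRecord(float(rng.uniform(30, 300)), False, True)
    if label == "over_5min":
        return OutcomeRecord(float(rng.uniform(301, 1200)), False, True)
    if label == "additional_technique":
        # every additional-technique case also runs over five minutes
        return OutcomeRecord(float(rng.uniform(301, 1200)), True, True)
    return OutcomeRecord(None, False, False)


def generate_dataset(config: SynthConfig) -> list[SynthSample]:
    """Generate a deterministic synthetic dataset from the config seed."""
    rng = np.random.default_rng(config.seed)
    classes = list(FOUR_CLASSES)
    samples: list[SynthSample] = []
    for _ in range(config.n_images):
        label = classes[int(rng.choice(4, p=config.class_mix))]
        if rng.random() < config.difficulty_feature_strength:
            visual = label
        else:
            visual = classes[int(rng.integers(4))]
        image, box, latent = _render_scene(config, visual, rng)
        outcome = _sample_outcome(label, rng)
        mapped = map_outcome(outcome)
        assert mapped.four_class == label
        samples.append(SynthSample(image=image, gt_box=box, outcome=outcome, label=mapped, latent=latent))
    return samples


def write_fixture(directory: str | Path, samples: Sequence[SynthSample]) -> None:
    """Write PNG images, box annotations (JSON + CSV) and outcomes CSV."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    names, boxes, outcomes = [], [], []
    for i, s in enumerate(samples):
        name = f"img_{i:05d}.png"
        ampio.write_image(directory / "images" / name, s.image)
        names.append(name)
        boxes.append(s.gt_box)
        outcomes.append(s.outcome)
    ampio.write_annotations_json(directory / "annotations.json", names, boxes)
    ampio.write_annotations_csv(directory / "annotations.csv", names, boxes)
    ampio.write_outcomes_csv(directory / "outcomes.csv", names, outcomes)


def read_fixture(directory: str | Path) -> list[SynthSample]:
    """Read a fixture directory back into samples (latents are not stored)."""
    directory = Path(directory)
    names, boxes = ampio.read_annotations_json(directory / "annotations.json")
    out_names, outcomes = ampio.read_outcomes_csv(directory / "outcomes.csv")
    by_name = dict(zip(out_names, outcomes))
    samples = []
    for name, box in zip(names, boxes):
        image = ampio.read_image(directory / "images" / name)
        outcome = by_name[name]
        samples.append(
            SynthSample(
                image=image,
                gt_box=box,
                outcome=outcome,
                label=map_outcome(outcome),
                latent={},
            )
        )
    return samples
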