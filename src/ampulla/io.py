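"""Readers and writers for the toolkit's interchange formats.

* Box annotations: COCO-style JSON ``[{"image": name, "bbox": [x, y, w, h]}]``
  and a flat CSV dialect ``image,x,y,w,h``; both round-trip coordinates
  bit-exactly (floats are serialized with ``repr`` precision).
* Outcome records: CSV ``image,cannulation_time_s,additional_technique,success``
  with an empty time field for failed cannulations.
* Soft masks: 8-bit grayscale PNG (``round(255 * p)``, for inspection) and
  lossless NPZ (authoritative for round trips).
* Success curves: CSV ``threshold,rate`` plus matplotlib PNG plots.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .geometry import BBox, SuccessCurve

__all__ = [
    "write_image",
    "read_image",
    "write_annotations_json",
    "read_annotations_json",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_outcomes_csv",
    "read_outcomes_csv",
    "write_mask_png",
    "read_mask_png",
    "write_mask_npz",
    "read_mask_npz",
    "write_success_curve_csv",
    "read_success_curve_csv",
    "plot_success_curves",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), image)


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


# -- annotations ------------------------------------------------------------


def write_annotations_json(path: str | Path, names: Sequence[str], boxes: Sequence[BBox]) -> None:
    records = [{"image": n, "bbox": list(b.as_tuple())} for n, b in zip(names, boxes)]
    Path(path).write_text(json.dumps(records, indent=1))


def read_annotations_json(path: str | Path) -> tuple[list[str], list[BBox]]:
    records = json.loads(Path(path).read_text())
    names = [r["image"] for r in records]
    boxes = [BBox(*r["bbox"]) for r in records]
    return names, boxes


def write_annotations_csv(path: str | Path, names: Sequence[str], boxes: Sequence[BBox]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "x", "y", "w", "h"])
        for n, b in zip(names, boxes):
            writer.writerow([n, repr(float(b.x)), repr(float(b.y)), repr(float(b.w)), repr(float(b.h))])


def read_annotations_csv(path: str | Path) -> tuple[list[str], list[BBox]]:
    names, boxes = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["image"])
            boxes.append(BBox(float(row["x"]), float(row["y"]), float(row["w"]), float(row["h"])))
    return names, boxes


# -- outcomes ---------------------------------------------------------------


def write_outcomes_csv(path: str | Path, names: Sequence[str], outcomes: Sequence) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "cannulation_time_s", "additional_technique", "success"])
        for n, o in zip(names, outcomes):
            t = "" if o.cannulation_time_s is None else repr(float(o.cannulation_time_s))
            writer.writerow([n, t, int(o.additional_technique), int(o.success)])


def read_outcomes_csv(path: str | Path):
    from .difficulty import OutcomeRecord

    names, outcomes = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["image"])
            t = None if row["cannulation_time_s"] == "" else float(row["cannulation_time_s"])
            outcomes.append(
                OutcomeRecord(t, bool(int(row["additional_technique"])), bool(int(row["success"])))
            )
    return names, outcomes


# -- masks ------------------------------------------------------------------


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), np.round(255.0 * np.asarray(mask)).astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.float64) / 255.0


def write_mask_npz(path: str | Path, mask: np.ndarray) -> None:
    np.savez_compressed(path, mask=np.asarray(mask, dtype=np.float64))


def read_mask_npz(path: str | Path) -> np.ndarray:
    return np.load(path)["mask"]


# -- success curves ---------------------------------------------------------


def write_success_curve_csv(path: str | Path, curve: SuccessCurve) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "rate"])
        for t, r in zip(curve.thresholds, curve.rates):
            writer.writerow([repr(float(t)), repr(float(r))])


def read_success_curve_csv(path: str | Path, metric_name: str = "iou") -> SuccessCurve:
    thresholds, rates = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            thresholds.append(float(row["threshold"]))
            rates.append(float(row["rate"]))
    return SuccessCurve(metric_name=metric_name, thresholds=tuple(thresholds), rates=tuple(rates))


def plot_success_curves(path: str | Path, curves: dict[str, SuccessCurve], title: str = "") -> None:
    """Plot labelled success curves to a PNG (threshold on x, rate on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    metric = None
    for label, curve in curves.items():
        ax.plot(curve.thresholds, curve.rates, marker="o", label=label)
        metric = curve.metric_name
    ax.set_xlabel(f"{metric} threshold")
    ax.set_ylabel("success rate")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
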