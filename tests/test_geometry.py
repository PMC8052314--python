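"""Box metrics: hand-computed examples, invariants, and pixel-count oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampulla.geometry import (
    BBox,
    DetectionEval,
    area_precision_recall,
    centroid_distance,
    compare_annotations,
    evaluate_pair,
    iou,
    success_curve,
)

from .oracles import (
    pixel_centroid_distance,
    pixel_iou,
    pixel_precision_recall,
    random_integer_box,
)


def boxes(max_xy=60, max_wh=40):
    return st.builds(
        BBox,
        x=st.integers(0, max_xy),
        y=st.integers(0, max_xy),
        w=st.integers(1, max_wh),
        h=st.integers(1, max_wh),
    )


class TestBBox:
    def test_rejects_nonpositive_extent(self):
        with pytest.raises(ValueError):
            BBox(0, 0, 0, 5)
        with pytest.raises(ValueError):
            BBox(0, 0, 5, -1)

    def test_centroid_and_area_are_derived(self):
        b = BBox(2, 3, 10, 4)
        assert (b.cx, b.cy) == (7.0, 5.0)
        assert b.area == 40.0


class TestIoU:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (BBox(0, 0, 10, 10), BBox(0, 0, 10, 10), 1.0),
            (BBox(0, 0, 10, 10), BBox(20, 20, 5, 5), 0.0),
            (BBox(0, 0, 10, 10), BBox(5, 0, 10, 10), 50 / 150),
        ],
    )
    def test_hand_computed(self, a, b, expected):
        assert iou(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(a=boxes(), b=boxes())
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        prec, rec = area_precision_recall(a, b)
        assert v <= prec + 1e-12 and v <= rec + 1e-12

    def test_equals_one_only_for_identical_boxes(self):
        a = BBox(1, 1, 5, 5)
        assert iou(a, BBox(1, 1, 5, 5)) == 1.0
        assert iou(a, BBox(1, 1, 5, 6)) < 1.0


class TestAreaPrecisionRecall:
    @pytest.mark.parametrize(
        "pred,gt,expected",
        [
            (BBox(3, 4, 7, 7), BBox(3, 4, 7, 7), (1.0, 1.0)),
            (BBox(0, 0, 20, 10), BBox(5, 2, 10, 5), (50 / 200, 1.0)),
            (BBox(0, 0, 10, 10), BBox(5, 0, 10, 10), (0.5, 0.5)),
        ],
    )
    def test_hand_computed(self, pred, gt, expected):
        assert area_precision_recall(pred, gt) == pytest.approx(expected, abs=1e-12)


class TestCentroidDistance:
    def test_identical_boxes_give_zero(self):
        b = BBox(10, 10, 8, 6)
        assert centroid_distance(b, b, 100, 100) == 0.0

    def test_direct_formula_evaluation(self):
        gt = BBox(45, 45, 10, 10)  # centroid (50, 50)
        est = BBox(55, 65, 10, 10)  # centroid (60, 70)
        assert centroid_distance(gt, est, 100, 100) == pytest.approx(0.15)

    def test_halving_image_size_doubles_distance(self):
        gt, est = BBox(10, 10, 4, 4), BBox(20, 16, 4, 4)
        assert centroid_distance(gt, est, 50, 50) == pytest.approx(
            2 * centroid_distance(gt, est, 100, 100)
        )

    def test_rejects_nonpositive_image(self):
        with pytest.raises(ValueError):
            centroid_distance(BBox(0, 0, 1, 1), BBox(0, 0, 1, 1), 0, 100)

    @settings(derandomize=True, max_examples=50)
    @given(a=boxes(), b=boxes(), dx=st.integers(-5, 5), dy=st.integers(-5, 5))
    def test_translation_covariance(self, a, b, dx, dy):
        d0 = centroid_distance(a, b, 200, 200)
        d1 = centroid_distance(a.shift(dx, dy), b.shift(dx, dy), 200, 200)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestSuccessCurve:
    def _evals(self, ious=(0.0,), cds=(0.0,)):
        n = max(len(ious), len(cds))
        ious = list(ious) + [0.0] * (n - len(ious))
        cds = list(cds) + [0.0] * (n - len(cds))
        return [DetectionEval(i, 1.0, 1.0, c) for i, c in zip(ious, cds)]

    def test_iou_counting(self):
        evals = self._evals(ious=(0.2, 0.4, 0.6))
        curve = success_curve(evals, "iou", [0.3])
        assert curve.rates == (pytest.approx(2 / 3),)

    def test_zero_threshold_with_positive_ious(self):
        evals = self._evals(ious=(0.1, 0.5, 0.9))
        assert success_curve(evals, "iou", [0.0]).rates == (1.0,)

    def test_centroid_counting(self):
        evals = self._evals(cds=(0.005, 0.03))
        assert success_curve(evals, "centroid_distance", [0.01]).rates == (0.5,)

    def test_monotonicity_on_random_samples(self, rng):
        ious = rng.uniform(0, 1, 50)
        cds = rng.uniform(0, 0.2, 50)
        evals = [DetectionEval(i, 1, 1, c) for i, c in zip(ious, cds)]
        iou_rates = success_curve(evals, "iou").rates
        cd_rates = success_curve(evals, "centroid_distance").rates
        assert all(a >= b for a, b in zip(iou_rates, iou_rates[1:]))
        assert all(a <= b for a, b in zip(cd_rates, cd_rates[1:]))

    def test_default_threshold_grids(self):
        evals = self._evals()
        assert success_curve(evals, "iou").thresholds == pytest.approx(np.arange(0, 0.91, 0.1))
        assert success_curve(evals, "centroid_distance").thresholds == pytest.approx(
            np.arange(0.01, 0.101, 0.01)
        )

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            success_curve(self._evals(), "mAP", [0.5])


class TestPixelOracle:
    """All analytic metrics must agree with painting boxes on a grid."""

    def test_metrics_match_rasterization(self, rng):
        grid = 128
        for _ in range(300):
            a = random_integer_box(rng, grid)
            b = random_integer_box(rng, grid)
            assert iou(a, b) == pytest.approx(pixel_iou(a, b, grid, grid), abs=1e-9)
            prec, rec = area_precision_recall(a, b)
            oprec, orec = pixel_precision_recall(a, b, grid, grid)
            assert (prec, rec) == pytest.approx((oprec, orec), abs=1e-9)
            assert centroid_distance(a, b, grid, grid) == pytest.approx(
                pixel_centroid_distance(a, b, grid, grid), abs=1e-9
            )


class TestCompareAnnotations:
    def test_identical_sets_are_perfect(self):
        boxes_ = [BBox(0, 0, 5, 5), BBox(10, 10, 8, 4)]
        s = compare_annotations(boxes_, boxes_, (100, 100))
        assert (s.mean.iou, s.mean.area_precision, s.mean.area_recall) == (1.0, 1.0, 1.0)
        assert s.mean.centroid_distance == 0.0

    def test_role_swap_swaps_precision_and_recall(self, rng):
        a = [random_integer_box(rng, 100) for _ in range(5)]
        b = [random_integer_box(rng, 100) for _ in range(5)]
        ab = compare_annotations(a, b, (100, 100))
        ba = compare_annotations(b, a, (100, 100))
        assert ab.mean.iou == pytest.approx(ba.mean.iou)
        assert ab.mean.centroid_distance == pytest.approx(ba.mean.centroid_distance)
        assert ab.mean.area_precision == pytest.approx(ba.mean.area_recall)
        assert ab.mean.area_recall == pytest.approx(ba.mean.area_precision)

    def test_means_match_per_image_average(self):
        a = [BBox(0, 0, 10, 10), BBox(5, 5, 10, 10), BBox(20, 20, 4, 4)]
        b = [BBox(0, 0, 10, 10), BBox(7, 5, 10, 10), BBox(21, 20, 4, 4)]
        s = compare_annotations(a, b, (100, 100))
        per_image = [evaluate_pair(x, y, 100, 100) for x, y in zip(a, b)]
        assert s.mean.iou == pytest.approx(np.mean([e.iou for e in per_image]))
        assert s.sd.iou == pytest.approx(np.std([e.iou for e in per_image]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_annotations([BBox(0, 0, 1, 1)], [], (10, 10))
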