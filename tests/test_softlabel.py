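"""Gaussian soft-mask rendering, peak-threshold decoding, and BCE."""

import numpy as np
import pytest

from ampulla.geometry import BBox, centroid_distance, iou
from ampulla.softlabel import (
    LEVEL_SET_FACTOR,
    DecodeSpec,
    GaussianLabelSpec,
    NoDetectionError,
    bce_loss,
    decode_mask_to_bbox,
    render_soft_mask,
)

from .oracles import brute_force_peak_component_box, random_area_fraction_box


class TestRender:
    def test_peak_at_centroid_pixel(self):
        box = BBox(20, 10, 16, 12)  # centroid (28, 16)
        mask = render_soft_mask(box, 64, 64)
        peak = np.unravel_index(np.argmax(mask), mask.shape)
        # centroid falls on a pixel-center cross: 4 pixels tie within quantization
        assert abs(peak[1] + 0.5 - box.cx) <= 0.5
        assert abs(peak[0] + 0.5 - box.cy) <= 0.5
        # peak equals 1 up to the half-pixel quantization of the grid
        assert mask.max() == pytest.approx(1.0, abs=0.01)

    def test_value_one_sigma_from_peak(self):
        box = BBox(24, 24, 16, 16)  # centroid (32, 32), sigma (8, 8)
        mask = render_soft_mask(box, 64, 64)
        # pixel center at (mu_x + sigma_x, mu_y): column 39 center is 39.5 < 40
        xs = np.arange(64) + 0.5
        col = int(np.argmin(np.abs(xs - (box.cx + 8))))
        row = int(np.argmin(np.abs(xs - box.cy)))
        expected = np.exp(-0.5 * ((xs[col] - box.cx) / 8) ** 2) * np.exp(
            -0.5 * ((xs[row] - box.cy) / 8) ** 2
        )
        assert mask[row, col] == pytest.approx(expected, rel=1e-12)
        assert np.exp(-0.5) == pytest.approx(0.6065, abs=5e-5)

    def test_doubling_width_doubles_level_set_distance(self):
        m1 = render_soft_mask(BBox(56, 56, 16, 16), 128, 128)
        m2 = render_soft_mask(BBox(48, 56, 32, 16), 128, 128)
        row = 63  # row through the centroid
        # horizontal distance at which the mask falls below 0.5
        d1 = np.sum(m1[row] > 0.5) / 2
        d2 = np.sum(m2[row] > 0.5) / 2
        assert d2 == pytest.approx(2 * d1, abs=1.0)

    def test_values_strictly_decrease_away_from_peak(self):
        # odd extents put the centroid exactly on a pixel center: unique peak
        mask = render_soft_mask(BBox(24, 24, 15, 17), 64, 64)
        pr, pc = np.unravel_index(np.argmax(mask), mask.shape)
        right = mask[pr, pc:]
        down = mask[pr:, pc]
        assert np.all(np.diff(right) < 0)
        assert np.all(np.diff(down) < 0)

    def test_reflection_symmetry_about_centroid(self):
        # centroid at the image center makes both flips exact symmetries
        mask = render_soft_mask(BBox(10, 14, 20, 16), 44, 40)  # centroid (20, 22)
        np.testing.assert_allclose(mask, mask[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(mask, mask[::-1], atol=1e-12)

    def test_var_half_extent_mode(self):
        box = BBox(24, 24, 16, 16)
        mask = render_soft_mask(box, 64, 64, GaussianLabelSpec("var_half_extent"))
        sigma = np.sqrt(8.0)  # sigma^2 = w/2
        xs = np.arange(64) + 0.5
        gauss = np.exp(-0.5 * ((xs - 32.0) / sigma) ** 2)
        np.testing.assert_allclose(mask, gauss[:, None] * gauss[None, :], rtol=1e-10)

    def test_box_outside_image_rejected(self):
        with pytest.raises(ValueError):
            render_soft_mask(BBox(60, 60, 10, 10), 64, 64)


class TestDecode:
    def test_single_hot_pixel(self):
        mask = np.zeros((16, 16))
        mask[5, 9] = 1.0
        box = decode_mask_to_bbox(mask)
        assert box.as_tuple() == (9.0, 5.0, 1.0, 1.0)

    def test_all_zero_mask_signals_no_detection(self):
        with pytest.raises(NoDetectionError):
            decode_mask_to_bbox(np.zeros((8, 8)))

    def test_two_bumps_keeps_only_peak_component(self):
        m = np.zeros((64, 64))
        m += 1.0 * render_soft_mask(BBox(8, 8, 10, 10), 64, 64)
        m += 0.8 * render_soft_mask(BBox(44, 44, 10, 10), 64, 64)
        box = decode_mask_to_bbox(m)
        oracle = brute_force_peak_component_box(m, 0.6)
        assert box.as_tuple() == tuple(float(v) for v in oracle)
        assert box.x2 < 30 and box.y2 < 30  # only the brighter bump

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(20):
            b1 = random_area_fraction_box(rng, 48, 0.02, 0.2)
            b2 = random_area_fraction_box(rng, 48, 0.02, 0.2)
            m = render_soft_mask(b1, 48, 48) + 0.7 * render_soft_mask(b2, 48, 48)
            got = decode_mask_to_bbox(m)
            assert got.as_tuple() == tuple(float(v) for v in brute_force_peak_component_box(m, 0.6))

    def test_invariant_to_positive_rescaling(self):
        m = render_soft_mask(BBox(10, 10, 12, 12), 48, 48)
        assert decode_mask_to_bbox(m) == decode_mask_to_bbox(0.037 * m)

    def test_peak_pixel_always_inside_box(self, rng):
        for _ in range(20):
            b = random_area_fraction_box(rng, 64, 0.02, 0.3)
            m = render_soft_mask(b, 64, 64)
            box = decode_mask_to_bbox(m, DecodeSpec(threshold=0.98))
            pr, pc = np.unravel_index(np.argmax(m), m.shape)
            assert box.x <= pc < box.x2 and box.y <= pr < box.y2

    def test_round_trip_recovers_box(self, rng):
        """decode(render(box)) matches the box up to the 0.6 level-set factor."""
        ratios, ious, cds = [], [], []
        for _ in range(60):
            b = random_area_fraction_box(rng, 128)
            got = decode_mask_to_bbox(render_soft_mask(b, 128, 128))
            ratios.append(got.w / b.w)
            ious.append(iou(b, got))
            cds.append(centroid_distance(b, got, 128, 128))
        assert min(ious) > 0.9
        assert max(cds) < 0.01
        assert 1.00 <= np.mean(ratios) <= 1.03
        assert LEVEL_SET_FACTOR == pytest.approx(1.0108, abs=5e-4)


class TestBCE:
    def test_uniform_half_against_itself_is_ln2(self):
        m = np.full((8, 8), 0.5)
        assert bce_loss(m, m) == pytest.approx(np.log(2), rel=1e-9)

    def test_minimized_when_prediction_equals_target(self, rng):
        t = rng.uniform(0.05, 0.95, size=(16, 16))
        base = bce_loss(t, t)
        for _ in range(5):
            perturbed = np.clip(t + rng.normal(0, 0.05, t.shape), 0, 1)
            assert bce_loss(perturbed, t) >= base

    def test_permutation_invariant(self, rng):
        p = rng.uniform(0, 1, size=(10, 10))
        t = rng.uniform(0, 1, size=(10, 10))
        perm = rng.permutation(100)
        assert bce_loss(p, t) == pytest.approx(
            bce_loss(p.ravel()[perm].reshape(10, 10), t.ravel()[perm].reshape(10, 10))
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((4, 4)), np.zeros((4, 5)))
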