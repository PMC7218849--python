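"""NDVI computation, threshold segmentation, orientation and petiole removal."""

import math

import numpy as np
import pytest

from leafmsi.segment import (
    NoLeafError,
    SegmentationParams,
    SegmentedLeaf,
    compute_ndvi,
    fit_orientation,
    remove_petiole,
    rotate_to_horizontal,
    threshold_segment,
    width_profile,
)
from leafmsi.stack import CalibratedStack, default_manifest


def stack_from_bands(nir, red, green=None, blue=None):
    nir = np.asarray(nir, dtype=float)
    z = np.zeros_like(nir)
    data = np.stack([nir, np.asarray(red, dtype=float), green if green is not None else z,
                     blue if blue is not None else z])
    return CalibratedStack(data, default_manifest())


class TestComputeNdvi:
    @pytest.mark.parametrize(
        "nir, red, expect",
        [(0.5, 0.5, 0.0), (0.8, 0.0, 1.0), (0.8, 0.1, 0.7778)],
    )
    def test_pointwise_values(self, nir, red, expect):
        s = stack_from_bands(np.full((4, 4), nir), np.full((4, 4), red))
        nd = compute_ndvi(s)
        assert nd.values[0, 0] == pytest.approx(expect, abs=1e-4)
        assert nd.valid.all()

    def test_zero_denominator_invalid(self):
        s = stack_from_bands(np.zeros((3, 3)), np.zeros((3, 3)))
        nd = compute_ndvi(s)
        assert not nd.valid.any()
        assert np.all(nd.values == 0.0)

    def test_values_bounded_on_valid_pixels(self):
        rng = np.random.default_rng(0)
        s = stack_from_bands(rng.uniform(-0.05, 1.5, (20, 20)), rng.uniform(-0.05, 1.5, (20, 20)))
        nd = compute_ndvi(s)
        assert np.all(np.abs(nd.values[nd.valid]) <= 1.0)

    def test_missing_band_role_rejected(self):
        from leafmsi.stack import BandInfo, FormatError

        data = np.zeros((2, 4, 4))
        s = CalibratedStack(data, [BandInfo(560, "green"), BandInfo(405, "blue")])
        with pytest.raises(FormatError):
            compute_ndvi(s)


class TestThresholdSegment:
    def make_scene(self, bg_ndvi=0.05, leaf_ndvi=0.7):
        h, w = 80, 120
        rows, cols = np.mgrid[0:h, 0:w]
        leaf = ((cols - 60) / 40) ** 2 + ((rows - 40) / 25) ** 2 <= 1
        nir = np.where(leaf, 0.8, 0.5)
        red = np.where(leaf, 0.8 * (1 - leaf_ndvi) / (1 + leaf_ndvi), 0.5 * (1 - bg_ndvi) / (1 + bg_ndvi))
        return stack_from_bands(nir, red), leaf

    def test_recovers_mask_exactly_on_clean_scene(self):
        stack, leaf = self.make_scene()
        seg = threshold_segment(stack, compute_ndvi(stack))
        inter = (seg.mask & leaf).sum()
        union = (seg.mask | leaf).sum()
        assert inter / union >= 0.99

    def test_all_background_raises_no_leaf(self):
        stack, _ = self.make_scene(leaf_ndvi=0.05)  # leaf below threshold too
        stack2 = stack_from_bands(np.full((10, 10), 0.5), np.full((10, 10), 0.48))
        with pytest.raises(NoLeafError):
            threshold_segment(stack2, compute_ndvi(stack2))

    def test_threshold_boundary_pixel_is_included(self):
        """NDVI exactly equal to t belongs to the leaf (>= in the rule)."""
        t = 0.25  # (0.625 - 0.375) / 1.0 is exact in binary floating point
        s = stack_from_bands(np.full((9, 9), 0.625), np.full((9, 9), 0.375))
        nd = compute_ndvi(s)
        assert nd.values[0, 0] == t
        seg = threshold_segment(s, nd, SegmentationParams(t=t))
        assert seg.mask.all()

    def test_masking_is_idempotent(self):
        stack, _ = self.make_scene()
        seg1 = threshold_segment(stack, compute_ndvi(stack))
        seg2 = threshold_segment(seg1.stack, compute_ndvi(seg1.stack))
        assert np.array_equal(seg1.mask, seg2.mask)
        assert np.allclose(seg1.stack.data, seg2.stack.data)

    def test_speckle_removed_by_largest_component(self):
        stack, leaf = self.make_scene()
        # add an above-threshold speck far from the leaf
        stack.data[0, 2:4, 2:4] = 0.9
        stack.data[1, 2:4, 2:4] = 0.05
        seg = threshold_segment(stack, compute_ndvi(stack))
        assert not seg.mask[2:4, 2:4].any()


def ellipse_mask(shape, center, a, b, theta_deg):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = cols - center[1]
    dy = -(rows - center[0])
    th = math.radians(theta_deg)
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1


class TestOrientation:
    def test_axis_aligned_is_zero(self):
        m = ellipse_mask((200, 300), (100, 150), 120, 50, 0)
        theta, deg = fit_orientation(m)
        assert abs(theta) < 0.5 and not deg

    @pytest.mark.parametrize("angle", [30.0, -40.0, 75.0])
    def test_rotated_ellipse_angle_recovered(self, angle):
        m = ellipse_mask((400, 400), (200, 200), 150, 60, angle)
        theta, _ = fit_orientation(m)
        assert theta == pytest.approx(angle, abs=1.0)

    def test_circle_degenerate_flag(self):
        m = ellipse_mask((200, 200), (100, 100), 70, 70, 0)
        theta, degenerate = fit_orientation(m)
        assert theta == 0.0 and degenerate

    def test_tiny_mask_rejected(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 4] = True
        with pytest.raises(ValueError, match="need >= 5"):
            fit_orientation(m)


class TestRotation:
    def make_seg(self, angle):
        m = ellipse_mask((400, 400), (200, 200), 150, 60, angle)
        data = np.broadcast_to(m, (4, 400, 400)).astype(float).copy()
        return SegmentedLeaf(CalibratedStack(data, default_manifest()), m)

    def test_zero_rotation_preserves_mask(self):
        seg = self.make_seg(0)
        rot = rotate_to_horizontal(seg, 0.0)
        inter = (rot.mask[:400, :400] & seg.mask).sum()
        union = (rot.mask[:400, :400] | seg.mask).sum()
        assert inter / union >= 0.995

    def test_rotation_brings_axis_horizontal(self):
        seg = self.make_seg(30)
        rot = rotate_to_horizontal(seg)
        theta, _ = fit_orientation(rot.mask)
        assert abs(theta) < 1.0
        assert rot.theta_deg == pytest.approx(30.0, abs=1.0)

    def test_rotation_conserves_area(self):
        seg = self.make_seg(30)
        rot = rotate_to_horizontal(seg)
        assert abs(rot.mask.sum() - seg.mask.sum()) / seg.mask.sum() < 0.02


class TestPetioleRemoval:
    def leaf_with_petiole(self, petiole_w=20):
        h, w = 300, 600
        m = ellipse_mask((h, w), (150, 220), 170, 90, 0)
        m[150 - petiole_w // 2 : 150 + petiole_w // 2, 380:540] = True
        data = np.broadcast_to(m, (4, h, w)).astype(float).copy()
        return SegmentedLeaf(CalibratedStack(data, default_manifest()), m), m.copy()

    def test_petiole_strip_removed(self):
        seg, _ = self.leaf_with_petiole()
        out = remove_petiole(seg, SegmentationParams(t_petiole=50))
        assert out.cut_col is not None
        # nothing left in the petiole-only region
        assert not out.mask[:, 420:].any()
        assert np.array_equal(out.stack.data[:, ~out.mask], np.zeros_like(out.stack.data[:, ~out.mask]))

    def test_wide_leaf_untouched_when_no_column_qualifies(self):
        h, w = 200, 400
        m = np.zeros((h, w), dtype=bool)
        m[40:160, 50:350] = True  # rectangle, min width 120 >= t
        data = np.broadcast_to(m, (4, h, w)).astype(float).copy()
        seg = SegmentedLeaf(CalibratedStack(data, default_manifest()), m)
        out = remove_petiole(seg, SegmentationParams(t_petiole=50))
        assert out.cut_col is None
        assert np.array_equal(out.mask, m)

    def test_tapering_tip_clipped_at_first_subthreshold_column(self):
        """Documented behavior: an ellipse tapering below t right of the
        widest column is clipped there."""
        seg, m = self.leaf_with_petiole(petiole_w=0)
        m[:, :] = False
        seg.mask[:, :] = False  # rebuild pure ellipse
        ell = ellipse_mask((300, 600), (150, 300), 250, 90, 0)
        seg = SegmentedLeaf(seg.stack, ell)
        widths = width_profile(ell)
        out = remove_petiole(seg, SegmentationParams(t_petiole=50))
        expected = next(
            c for c in range(int(np.argmax(widths)) + 1, 600) if widths[c] < 50
        )
        assert out.cut_col == expected

    @pytest.mark.parametrize("t_small, t_large", [(20, 50), (50, 120)])
    def test_monotone_in_threshold(self, t_small, t_large):
        seg, _ = self.leaf_with_petiole()
        small = remove_petiole(seg, SegmentationParams(t_petiole=t_small))
        large = remove_petiole(seg, SegmentationParams(t_petiole=t_large))
        assert large.mask.sum() <= small.mask.sum()


def test_end_to_end_segmentation_on_simulated_scene(processed_noiseless):
    from conftest import rotate_truth_mask

    _, gt, _, result = processed_noiseless
    truth = rotate_truth_mask(gt.leaf_mask, result.leaf.theta_deg)
    inter = (result.leaf.mask & truth).sum()
    union = (result.leaf.mask | truth).sum()
    assert inter / union >= 0.99
    petiole = rotate_truth_mask(gt.petiole_mask, result.leaf.theta_deg)
    assert (result.leaf.mask & petiole).sum() / petiole.sum() < 0.01
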