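"""Contour-ring sectioning: scaling center, nested contours, partition,
per-section means and the edge-to-center gradient direction."""

import numpy as np
import pytest

from leafmsi.calibrate import CalibrationBundle, spectral_calibrate
from leafmsi.sections import (
    SectioningParams,
    scaled_contours,
    scaling_center,
    section_leaf,
    section_means,
    section_partition,
)
from leafmsi.segment import compute_ndvi
from leafmsi.simulate import (
    BandTransmittance,
    SceneParams,
    default_band_transmittance,
    generate_scene,
)

from conftest import scene_bundle


def ellipse(shape, center, a, b):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((cols - center[1]) / a) ** 2 + ((rows - center[0]) / b) ** 2 <= 1


class TestScalingCenter:
    def test_two_thirds_from_tip(self):
        m = ellipse((600, 800), (300, 400), 300, 120)  # cols 100..700
        row, col = scaling_center(m)
        assert row == pytest.approx(300, abs=1)
        assert col == pytest.approx(100 + (2 / 3) * 600, abs=1.5)

    def test_symmetric_mask_center_on_symmetry_row(self):
        m = ellipse((400, 600), (207, 300), 200, 90)
        row, _ = scaling_center(m)
        assert row == pytest.approx(207, abs=1)

    def test_half_fraction_is_centroid_column(self):
        m = ellipse((400, 600), (200, 300), 200, 90)
        _, col = scaling_center(m, SectioningParams(center_fraction=0.5))
        assert col == pytest.approx(300, abs=1.5)

    def test_tip_side_right_mirrors(self):
        m = ellipse((400, 600), (200, 300), 200, 90)  # cols 100..500
        _, col = scaling_center(m, SectioningParams(tip_side="right"))
        assert col == pytest.approx(500 - (2 / 3) * 400, abs=1.5)


class TestScaledContours:
    def test_shrinks_toward_center(self):
        t = np.linspace(0, 2 * np.pi, 100)
        circle = np.column_stack([50 + 30 * np.sin(t), 50 + 30 * np.cos(t)])
        rings = scaled_contours(circle, (50.0, 50.0), SectioningParams(scale_factors=(0.5,)))
        radii = np.hypot(rings[0][:, 0] - 50, rings[0][:, 1] - 50)
        assert np.allclose(radii, 15.0)

    def test_ellipse_area_scales_quadratically(self):
        from leafmsi.features import leaf_contour, _polygon_area

        m = ellipse((400, 600), (200, 300), 200, 90)
        c = leaf_contour(m)
        a0 = _polygon_area(c)
        for s in (0.9, 0.5, 0.3):
            ring = scaled_contours(c, (200.0, 300.0), SectioningParams(scale_factors=(s,)))[0]
            assert _polygon_area(ring) == pytest.approx(s**2 * a0, rel=0.01)


class TestPartition:
    def test_eight_sections_partition_convex_leaf(self):
        m = ellipse((400, 620), (200, 310), 280, 150)
        labels, means = section_leaf(m, np.full(m.shape, 0.7))
        present = np.unique(labels[m])
        assert list(present) == list(range(1, 9))
        assert (labels[m] > 0).all()
        assert (labels[~m] == 0).all()
        assert np.allclose(means, 0.7)

    def test_circle_sections_match_annulus_areas(self):
        """Scaling a circle about its own center yields exact annuli."""
        m = ellipse((600, 600), (300, 300), 250, 250)
        from leafmsi.features import leaf_contour

        c = leaf_contour(m)
        params = SectioningParams()
        rings = scaled_contours(c, (300.0, 300.0), params)
        labels = section_partition(m, rings, params)
        total = m.sum()
        factors = (1.0,) + params.scale_factors + (0.0,)
        for k in range(1, 9):
            frac_expected = factors[k - 1] ** 2 - factors[k] ** 2
            frac = (labels == k).sum() / total
            assert frac == pytest.approx(frac_expected, abs=0.02)

    def test_concave_mask_every_pixel_labeled_once(self):
        m = ellipse((400, 600), (200, 300), 250, 120)
        m &= ~ellipse((400, 600), (200, 420), 60, 60)  # bite: concave contour
        labels, _ = section_leaf(m, np.zeros(m.shape))
        assert (labels[m] > 0).all()
        assert (labels[~m] == 0).all()


class TestSectionMeans:
    def test_toy_mask_means_equal_brute_force_exactly(self):
        ndvi = np.arange(36, dtype=float).reshape(6, 6) / 36.0
        labels = np.zeros((6, 6), dtype=int)
        labels[1:5, 1:3] = 1
        labels[1:5, 3:5] = 2
        means = section_means(ndvi, labels)
        for k in (1, 2):
            assert means[k - 1] == ndvi[labels == k].mean()  # exact

    def test_empty_section_reported_missing(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[1, 1] = 1
        labels[2, 2] = 3  # section 2 empty
        means = section_means(np.ones((5, 5)), labels)
        assert np.isnan(means[1])
        assert means[0] == 1.0


def _vein_free_scene(seed, gradient):
    tau = default_band_transmittance()
    tau[880] = BandTransmittance(0.80, 0.80, 0.97)
    tau[660] = BandTransmittance(0.10, 0.10, 0.95)
    return SceneParams(
        seed=seed, noise_sd=0.0, band_transmittance=tau, ndvi_gradient=gradient
    )


class TestGradientRecovery:
    def test_section_means_increase_edge_to_center(self):
        params = _vein_free_scene(2, 0.1)
        raw, white, dark, gt = generate_scene(params)
        cal = spectral_calibrate(raw, scene_bundle(white, dark, params))
        nd = compute_ndvi(cal)
        _, means = section_leaf(gt.leaf_mask, nd.values)
        assert np.all(np.diff(means) > 0)

    def test_stronger_gradient_widens_center_minus_edge(self):
        gaps = []
        for g in (0.02, 0.06, 0.12):
            params = _vein_free_scene(4, g)
            raw, white, dark, gt = generate_scene(params)
            cal = spectral_calibrate(raw, scene_bundle(white, dark, params))
            nd = compute_ndvi(cal)
            _, means = section_leaf(gt.leaf_mask, nd.values)
            gaps.append(means[-1] - means[0])
        assert gaps[0] < gaps[1] < gaps[2]
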