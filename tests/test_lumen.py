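"""Lumen detection: binarization, polar transform, border tracking, areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import ndimage

from octstent.lumen import (
    LumenContour,
    PolarFrame,
    apply_validity_region,
    binarize_and_clean,
    detect_raw_border,
    fill_and_smooth,
    lumen_area,
    lumen_volume,
    to_polar,
)

from conftest import disk_image


def contour_from_radius(radius_um, frame_index=0):
    """Assemble a LumenContour directly from a per-θ radius table (μm)."""
    return fill_and_smooth(
        np.asarray(radius_um, dtype=float),
        None,
        pixel_size=1.0,
        frame_index=frame_index,
        small_smooth_span=0.0,
    )


class TestBinarize:
    def test_speck_removed_wall_kept(self):
        img = np.zeros((64, 64))
        img[30:40, 10:60] = 200.0  # wall slab
        img[5, 5] = 255.0  # 1-px speck
        img[6, 5] = 255.0
        out = binarize_and_clean(img, opening_radius=3, min_area=30)
        _, n = ndimage.label(out)
        assert n == 1
        assert not out[5, 5]
        assert out[35, 30]

    def test_all_background_frame_gives_empty_mask(self):
        assert not binarize_and_clean(np.zeros((32, 32))).any()

    def test_disabled_operators_reduce_to_plain_threshold(self):
        img = np.zeros((32, 32))
        img[10, 10] = 255.0
        out = binarize_and_clean(img, opening_radius=0, min_area=0)
        assert out.sum() == 1 and out[10, 10]


class TestToPolar:
    def test_centered_disk_has_constant_transition_radius(self):
        polar = to_polar(disk_image(radius=50), origin=(64, 64), n_theta=180)
        border = (polar.image > 0.5).argmin(axis=0)  # first row outside the disk
        assert np.all(np.abs(border - 50) <= 1)

    def test_uniform_image_maps_to_uniform_polar(self):
        polar = to_polar(np.full((64, 64), 37.0), origin=(32, 32))
        np.testing.assert_allclose(polar.image, 37.0)

    def test_origin_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="origin"):
            to_polar(np.zeros((32, 32)), origin=(40, 10))

    def test_round_trip_with_independent_inverse_map(self):
        """Polar→Cartesian resampling (oracle) reproduces a smooth image."""
        size = 128
        rows, cols = np.mgrid[0:size, 0:size]
        img = 100 + 80 * np.exp(-((rows - 50.0) ** 2 + (cols - 70.0) ** 2) / 800.0)
        origin = (size // 2, size // 2)
        n_theta = 720
        polar = to_polar(img, origin, n_theta=n_theta)
        # inverse map: sample the polar image back onto the Cartesian grid
        dy = origin[0] - rows
        dx = cols - origin[1]
        rr = np.hypot(dx, dy)
        tt = (np.degrees(np.arctan2(dy, dx)) % 360.0) * n_theta / 360.0
        polar_wrapped = np.hstack([polar.image, polar.image[:, :1]])
        back = ndimage.map_coordinates(polar_wrapped, [rr, tt], order=1, mode="nearest")
        valid = (rr > 3) & (rr < polar.r_max - 1)
        assert np.abs(back - img)[valid].mean() < 2.0


class TestRawBorder:
    def test_disk_transition_detected_on_every_scan(self):
        polar = to_polar(disk_image(radius=50), origin=(64, 64), n_theta=180)
        binary = PolarFrame((polar.image > 0.5).astype(float), polar.origin, 1.0)
        border = detect_raw_border(binary)
        assert not np.isnan(border).any()
        assert np.all(np.abs(border - 50) <= 1)

    def test_empty_frame_is_all_missing(self):
        polar = PolarFrame(np.zeros((60, 90)), (0, 0), 1.0)
        assert np.isnan(detect_raw_border(polar)).all()

    def test_noise_pixel_hijacks_scan_without_validity_region(self):
        """A lone bright pixel closer than the wall wins first-edge detection —
        the failure mode the inter-frame validity region exists to remove."""
        img = np.zeros((80, 36))
        img[50:, :] = 1.0  # true border at r=50
        img[10, 7] = 1.0  # noise on one A-scan
        border = detect_raw_border(PolarFrame(img, (0, 0), 1.0))
        assert border[7] < 12
        # the Sobel kernel spreads one bin sideways; scans beyond the
        # immediate neighbours still find the true border
        far = np.setdiff1d(np.arange(36), [6, 7, 8])
        assert np.all(np.abs(border[far] - 50) <= 1)


class TestValidityRegion:
    def test_candidates_on_previous_border_pass(self):
        prev = np.full(36, 50.0)
        out = apply_validity_region(prev.copy(), prev, width=10)
        np.testing.assert_array_equal(out, prev)

    def test_displacement_beyond_half_width_removed(self):
        prev = np.full(36, 50.0)
        cand = prev.copy()
        cand[5] += 20
        out = apply_validity_region(cand, prev, width=10)
        assert np.isnan(out[5]) and not np.isnan(np.delete(out, 5)).any()

    def test_displacement_within_half_width_kept(self):
        prev = np.full(36, 50.0)
        out = apply_validity_region(prev + 3.0, prev, width=10)
        assert not np.isnan(out).any()

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            apply_validity_region(np.zeros(4), np.zeros(4), width=0)

    @given(hst.integers(min_value=1, max_value=20))
    @settings(deadline=None)
    def test_shrinking_width_never_retains_more(self, width):
        rng = np.random.default_rng(7)
        prev = np.full(90, 50.0)
        cand = prev + rng.normal(0, 6, 90)
        wide = np.isnan(apply_validity_region(cand, prev, width + 1)).sum()
        narrow = np.isnan(apply_validity_region(cand, prev, width)).sum()
        assert narrow >= wide


class TestFillAndSmooth:
    def test_complete_candidates_flag_no_bifurcation(self):
        c = contour_from_radius(np.full(360, 80.0))
        assert not c.bifurcation_flag
        np.testing.assert_allclose(c.radius, 80.0)

    def test_small_gap_interpolates_between_equal_endpoints(self):
        cand = np.full(360, 80.0)
        cand[100:130] = np.nan  # 30° wedge
        c = fill_and_smooth(cand, None, pixel_size=1.0)
        assert not c.bifurcation_flag
        np.testing.assert_allclose(c.radius, 80.0)

    def test_wide_gap_filled_from_previous_slice_and_flagged(self):
        prev = contour_from_radius(np.full(360, 75.0))
        cand = np.full(360, 80.0)
        cand[100:165] = np.nan  # 65° wedge, beyond the 50° threshold
        c = fill_and_smooth(cand, prev, pixel_size=1.0)
        assert c.bifurcation_flag
        assert (c.radius > 0).all()
        # interior of the gap carries the previous slice's radius
        assert abs(c.radius[130] - 75.0) < 2.0
        # smoothing blends the seam without destroying the rest of the border
        assert abs(c.radius[300] - 80.0) < 1.0

    def test_no_candidates_and_no_previous_contour_rejected(self):
        with pytest.raises(ValueError, match="previous"):
            fill_and_smooth(np.full(360, np.nan), None)

    def test_contour_is_circularly_continuous(self, segmented_noisy):
        result, _ = segmented_noisy
        for c in result.contours:
            dr = np.abs(np.diff(c.radius))
            wrap = abs(c.radius[0] - c.radius[-1])
            assert wrap <= max(dr.max(), 1e-9)


class TestAreaVolume:
    def test_circle_area_matches_pi_r_squared(self):
        c = contour_from_radius(np.full(360, 1500.0))
        assert lumen_area(c) == pytest.approx(np.pi * 1.5**2, rel=1e-3)

    def test_area_scales_quadratically_with_radius(self):
        small = contour_from_radius(np.full(360, 700.0))
        big = contour_from_radius(np.full(360, 1400.0))
        assert lumen_area(big) == pytest.approx(4 * lumen_area(small), rel=1e-9)

    def test_ellipse_area_matches_analytic_value(self):
        a, b = 1900.0, 1450.0
        theta = np.deg2rad(np.arange(360))
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        c = contour_from_radius(r)
        assert lumen_area(c) == pytest.approx(np.pi * 1.9 * 1.45, rel=1e-3)

    def test_volume_sums_area_times_spacing(self):
        c = contour_from_radius(np.full(360, 1261.566))  # area ≈ 5 mm²
        area = lumen_area(c)
        contours = [c] * 10
        assert lumen_volume(contours, 100.0) == pytest.approx(10 * area * 0.1)
        assert lumen_volume([c], 100.0) == pytest.approx(area * 0.1)
        with pytest.raises(ValueError):
            lumen_volume([], 100.0)
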