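"""Puncta detection, mitophagy-reporter classification, FWHM, densities."""

import numpy as np
import pytest

from mitoquant.puncta import (
    Punctum,
    classify_cargo,
    classify_mcherry_only,
    detect_puncta,
    linescan_fwhm,
    max_project,
    parkin_positive_area,
    puncta_density_on_mask,
    region_mean_intensity,
    subtract_background,
)
from mitoquant.synth import render_spot

PX = 0.1  # μm


def _spot_plane(centers_um, sigma=0.08, amp=200.0, shape=(64, 64), px=PX):
    plane = np.zeros(shape)
    for c in centers_um:
        plane += render_spot(c, sigma, amp, shape, px).data[0]
    return plane


class TestMaxProject:
    def test_unit_z_is_identity(self, rng):
        plane = rng.random((1, 8, 8))
        assert np.array_equal(max_project(plane), plane[0])

    def test_constant_volume(self):
        assert np.all(max_project(np.full((4, 8, 8), 3.0)) == 3.0)

    def test_single_bright_voxel(self):
        vol = np.zeros((5, 8, 8))
        vol[3, 2, 6] = 9.0
        mip = max_project(vol)
        assert mip[2, 6] == 9.0 and mip.sum() == 9.0


class TestSubtractBackground:
    def test_constant_plane_goes_to_zero(self):
        out = subtract_background(np.full((32, 32), 57.0), 0.5, PX)
        assert np.all(out == 0.0)

    def test_spot_plus_offset_recovers_spot(self):
        spot = _spot_plane([(2.0, 2.0)])
        out = subtract_background(spot + 40.0, 0.5, PX)
        assert np.abs(out - spot).max() < 0.05 * spot.max()

    def test_output_never_exceeds_input(self, rng):
        plane = rng.poisson(100, (32, 32)).astype(float)
        out = subtract_background(plane, 0.5, PX)
        assert np.all(out <= plane) and np.all(out >= 0)

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError, match="pixel"):
            subtract_background(np.zeros((8, 8)), 0.05, PX)


class TestDetectPuncta:
    def test_seven_above_three_below_size_filter(self):
        """7 extended spots pass the strict size filter; 3 single-pixel
        specks below it do not.  Areas verified by brute-force pixel
        counting."""
        centers = [(1.0, 1.0), (1.0, 3.0), (1.0, 5.0), (3.0, 1.0),
                   (3.0, 3.0), (3.0, 5.0), (5.0, 3.0)]
        plane = _spot_plane(centers, sigma=0.12)
        for y, x in [(55, 5), (58, 30), (60, 55)]:
            plane[y, x] = 300.0
        min_area = 0.02  # μm²; specks are 1 px = 0.01 μm²
        spots = detect_puncta(plane, PX, threshold=50.0, min_area=min_area)
        assert len(spots) == 7
        mask = plane > 50.0
        from skimage.measure import label, regionprops

        brute = [p.area for p in regionprops(label(mask, connectivity=2))]
        assert sorted(a for a in brute if a * PX**2 > min_area) == sorted(
            round(s.area / PX**2) for s in spots
        )

    def test_blank_plane_yields_empty_list(self):
        assert detect_puncta(np.zeros((16, 16)), PX) == []

    def test_count_invariant_to_constant_offset(self):
        plane = _spot_plane([(1.5, 1.5), (4.0, 4.5)])
        def count(p):
            return len(detect_puncta(subtract_background(p, 0.5, PX), PX, threshold=50.0))
        assert count(plane) == count(plane + 500.0) == 2


class TestMcherryOnly:
    def _punctum(self, y, x):
        return Punctum(centroid=(y, x), area=0.05, peak=0.0, background=0.0)

    # spot centered on a pixel center so the profile samples the true peak
    C = (32 + 0.5) * PX

    def _planes(self, mch_peak, gfp_peak, bg=100.0):
        shape = (64, 64)
        mch = np.full(shape, bg) + _spot_plane([(self.C, self.C)], amp=mch_peak - bg)
        gfp = np.full(shape, bg) + (
            _spot_plane([(self.C, self.C)], amp=gfp_peak - bg) if gfp_peak > bg else 0.0
        )
        return gfp, mch

    def test_two_to_one_over_background_is_positive(self):
        # peak 300 over background 100 measures ρ = 2.0 (the criterion value)
        gfp, mch = self._planes(mch_peak=300.0, gfp_peak=0.0)
        p = classify_mcherry_only(self._punctum(self.C, self.C), gfp, mch, PX)
        assert p.ratios["mcherry"] == pytest.approx(2.0, abs=0.05)
        # clearly above the 2:1 criterion: classified mCherry-only
        gfp, mch = self._planes(mch_peak=320.0, gfp_peak=0.0)
        p = classify_mcherry_only(self._punctum(self.C, self.C), gfp, mch, PX)
        assert p.flags["mcherry_only"] and not p.flags["gfp_positive"]

    def test_gfp_positive_punctum_is_not_mcherry_only(self):
        gfp, mch = self._planes(mch_peak=300.0, gfp_peak=300.0)
        p = classify_mcherry_only(self._punctum(self.C, self.C), gfp, mch, PX)
        assert p.flags["gfp_positive"] and not p.flags["mcherry_only"]

    def test_weak_mcherry_fails_ratio(self):
        gfp, mch = self._planes(mch_peak=150.0, gfp_peak=0.0)
        p = classify_mcherry_only(self._punctum(self.C, self.C), gfp, mch, PX)
        assert p.ratios["mcherry"] == pytest.approx(0.5, abs=0.03)
        assert not p.flags["mcherry_only"]

    def test_nonpositive_background_excludes_with_reason(self):
        gfp = np.zeros((64, 64))
        mch = _spot_plane([(3.2, 3.2)], amp=300.0)  # zero background
        p = classify_mcherry_only(self._punctum(self.C, self.C), gfp, mch, PX)
        assert "excluded" in p.flags and not p.flags["mcherry_only"]


class TestLinescanFwhm:
    def test_gaussian_spot_gives_150_nm(self):
        px, sigma = 0.02, 0.0637
        vol = render_spot((1.0, 1.0), sigma, 500.0, (100, 100), px)
        res = linescan_fwhm(vol.data[0], (1.0, 0.1), (1.0, 1.9), px)
        assert res.defined
        assert res.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, rel=0.05)

    def test_doubling_sigma_doubles_fwhm(self):
        px = 0.02
        f = []
        for sigma in (0.06, 0.12):
            vol = render_spot((2.0, 2.0), sigma, 500.0, (200, 200), px)
            f.append(linescan_fwhm(vol.data[0], (2.0, 0.2), (2.0, 3.8), px).fwhm)
        assert f[1] / f[0] == pytest.approx(2.0, rel=0.03)

    def test_flat_profile_is_undefined(self):
        res = linescan_fwhm(np.full((16, 16), 5.0), (0.5, 0.1), (0.5, 1.2), PX)
        assert not res.defined and np.isnan(res.fwhm)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError):
            linescan_fwhm(np.zeros((8, 8)), (0.2, 0.2), (0.2, 0.2), PX)


class TestClassifyCargo:
    def test_pair_within_radius_is_dual(self):
        out = classify_cargo([(1.00, 1.00)], [(1.05, 1.00)], 0.15)
        assert out == {"A_only": 0, "B_only": 0, "dual": 1}

    def test_pair_outside_radius_stays_single(self):
        out = classify_cargo([(1.00, 1.00)], [(1.30, 1.00)], 0.15)
        assert out == {"A_only": 1, "B_only": 1, "dual": 0}

    def test_unmatched_population(self):
        spots = [(0.1 * i, 0.0) for i in range(100)]
        out = classify_cargo(spots, [], 0.15)
        assert out == {"A_only": 100, "B_only": 0, "dual": 0}

    def test_each_spot_used_at_most_once(self):
        # two A spots compete for one B spot: closest wins, other stays single
        out = classify_cargo([(1.0, 1.0), (1.1, 1.0)], [(1.02, 1.0)], 0.15)
        assert out == {"A_only": 1, "B_only": 0, "dual": 1}


class TestDensitiesAndMeans:
    def test_density_counts_per_area(self):
        mask = np.zeros((20, 20), bool)
        mask[:10, :20] = True  # 200 px = 2 μm²
        spots = [(0.5, 0.5), (0.5, 1.5), (0.2, 0.8), (0.9, 1.9)]
        assert puncta_density_on_mask(spots, mask, PX) == pytest.approx(2.0)

    def test_off_mask_spots_do_not_count(self):
        mask = np.zeros((20, 20), bool)
        mask[:10] = True
        assert puncta_density_on_mask([(1.5, 0.5)], mask, PX) == 0.0
        with pytest.raises(ValueError, match="zero"):
            puncta_density_on_mask([], np.zeros((4, 4), bool), PX)

    def test_density_invariant_to_pixel_size(self):
        # same physical disk mask and spot positions at two samplings
        def density(px):
            n = int(round(2.0 / px))
            yy, xx = np.mgrid[0:n, 0:n]
            mask = ((yy + 0.5) * px - 1.0) ** 2 + ((xx + 0.5) * px - 1.0) ** 2 <= 0.8**2
            spots = [(1.0, 1.0), (1.3, 0.8), (0.6, 1.2)]
            return puncta_density_on_mask(spots, mask, px)

        assert density(0.1) == pytest.approx(density(0.05), rel=0.05)

    def test_region_mean(self):
        plane = np.zeros((10, 10))
        plane[:5] = 10.0
        mask = np.ones((10, 10), bool)
        assert region_mean_intensity(plane, mask) == pytest.approx(5.0)
        assert region_mean_intensity(np.full((4, 4), 7.0), np.ones((4, 4), bool)) == 7.0
        with pytest.raises(ValueError, match="empty"):
            region_mean_intensity(plane, np.zeros((10, 10), bool))

    def test_mean_ignores_pixels_outside_mask(self, rng):
        plane = rng.random((12, 12))
        mask = np.zeros((12, 12), bool)
        mask[3:6, 3:6] = True
        outside = plane.copy()
        outside[~mask] = 1e6
        assert region_mean_intensity(plane, mask) == region_mean_intensity(outside, mask)


class TestParkinArea:
    def test_subthreshold_plane_has_zero_area(self):
        mask = np.ones((16, 16), bool)
        assert parkin_positive_area(np.full((16, 16), 5.0), 10.0, mask, PX) == 0.0

    def test_disk_area_is_pi_r_squared(self):
        n = 64
        yy, xx = np.mgrid[0:n, 0:n]
        disk = (((yy + 0.5) * PX - 3.2) ** 2 + ((xx + 0.5) * PX - 3.2) ** 2) <= 1.0**2
        plane = np.where(disk, 100.0, 0.0)
        area = parkin_positive_area(plane, 50.0, np.ones((n, n), bool), PX)
        assert area == pytest.approx(np.pi, rel=0.03)

    def test_area_monotone_in_threshold(self, rng):
        plane = rng.poisson(100, (32, 32)).astype(float)
        mask = np.ones((32, 32), bool)
        areas = [parkin_positive_area(plane, t, mask, PX) for t in (80, 100, 120)]
        assert areas[0] >= areas[1] >= areas[2]
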