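"""HU masking, SUVpeak, threshold segmentation and partial volume correction."""

import numpy as np
import pytest
from scipy import ndimage

from graftquant import HUWindow, hu_mask, suv_peak, graft_threshold, \
    threshold_segment, pvc_correct, patient_graft_uptake
from graftquant.quantify import InsufficientVolumeError, _sphere_offsets

from conftest import (
    brute_force_suv_peak,
    brute_force_threshold_segment,
    make_ct_volume,
    make_suv_volume,
)


class TestHUMask:
    def test_uniform_muscle_keeps_voi(self):
        ct = make_ct_volume(np.full((10, 10, 10), 50.0))
        voi = np.zeros((10, 10, 10), bool)
        voi[2:8, 2:8, 2:8] = True
        out = hu_mask(ct, voi, HUWindow(0, 250))
        np.testing.assert_array_equal(out, voi)

    def test_two_block_phantom_keeps_muscle_half(self):
        vox = np.full((10, 10, 10), 50.0)
        vox[5:] = 700.0  # bone half
        ct = make_ct_volume(vox)
        voi = np.ones((10, 10, 10), bool)
        out = hu_mask(ct, voi, HUWindow(0, 250))
        assert out[:5].all() and not out[5:].any()
        assert out.sum() == 500

    def test_fat_voi_is_empty_with_warning(self):
        ct = make_ct_volume(np.full((6, 6, 6), -100.0))
        voi = np.ones((6, 6, 6), bool)
        with pytest.warns(UserWarning, match="empty"):
            out = hu_mask(ct, voi, HUWindow(0, 250))
        assert not out.any()

    def test_window_bounds_inclusive(self):
        ct = make_ct_volume(np.array([[[0.0, 250.0, -0.5, 250.5]]]))
        voi = np.ones((1, 1, 4), bool)
        out = hu_mask(ct, voi, HUWindow(0, 250))
        assert out.tolist() == [[[True, True, False, False]]]

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            HUWindow(250, 0)


class TestSUVPeak:
    def test_constant_field(self):
        vol = make_suv_volume(np.full((10, 10, 10), 2.0))
        mask = np.ones((10, 10, 10), bool)
        assert suv_peak(vol, mask) == pytest.approx(2.0, abs=1e-12)

    def test_single_hot_voxel_closed_form(self):
        vox = np.ones((15, 15, 15))
        vox[7, 7, 7] = 10.0
        vol = make_suv_volume(vox, spacing=(2, 2, 2))
        mask = np.ones((15, 15, 15), bool)
        k = len(_sphere_offsets((2, 2, 2), 1.0))
        expected = (10.0 + (k - 1) * 1.0) / k
        assert suv_peak(vol, mask) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vox = rng.uniform(0, 8, (15, 15, 15))
        mask = rng.random((15, 15, 15)) < 0.6
        vol = make_suv_volume(vox, spacing=(2, 2, 2))
        expected, _ = brute_force_suv_peak(vox, mask, (2, 2, 2))
        assert suv_peak(vol, mask) == pytest.approx(expected, abs=1e-12)

    def test_mask_smaller_than_sphere_rejected(self):
        vol = make_suv_volume(np.ones((10, 10, 10)), spacing=(1, 1, 1))
        mask = np.zeros((10, 10, 10), bool)
        mask[5, 5, 5] = True  # 0.001 mL << 1 mL
        with pytest.raises(InsufficientVolumeError):
            suv_peak(vol, mask)


class TestGraftThreshold:
    def test_equal_sides(self):
        assert graft_threshold(1.2, 1.2) == pytest.approx(1.2)

    def test_rules(self):
        assert graft_threshold(1.0, 1.4, "mean") == pytest.approx(1.2)
        assert graft_threshold(1.0, 1.4, "max") == pytest.approx(1.4)
        assert graft_threshold(1.0, 1.4, "per-side") == (1.0, 1.4)

    def test_missing_side(self):
        assert graft_threshold(1.0, None, "mean") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            graft_threshold(1.0, None, "per-side")
        with pytest.raises(ValueError):
            graft_threshold(None, None, "mean")

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            graft_threshold(1.0, 1.0, "median")


class TestThresholdSegment:
    def test_uniform_voi(self):
        vol = make_suv_volume(np.full((10, 10, 10), 3.0))
        voi = np.zeros((10, 10, 10), bool)
        voi[1:9, 1:9, 1:9] = True
        seg = threshold_segment(vol, voi, 2.0)
        np.testing.assert_array_equal(seg.mask, voi)
        assert seg.suv_mean == pytest.approx(3.0)
        assert seg.suv_total == pytest.approx(3.0 * voi.sum() * vol.voxel_volume_ml)

    def test_single_voxel_removed(self):
        vox = np.ones((12, 12, 12))
        vox[6, 6, 6] = 10.0  # isolated 0.008 mL voxel above threshold
        vol = make_suv_volume(vox, spacing=(2, 2, 2))
        seg = threshold_segment(vol, np.ones_like(vox, bool), 5.0)
        assert seg.volume_ml == 0.0
        assert seg.suv_total == 0.0
        assert seg.components == []

    def test_small_blob_filtered_large_kept(self):
        vox = np.zeros((20, 20, 20))
        vox[2:4, 2:4, 2:4] = 5.0       # 8 voxels * 0.0625 mL = 0.5 mL
        vox[10:14, 10:14, 10:12] = 5.0  # 32 voxels * 0.0625 mL = 2.0 mL
        # voxel volume 2.5*2.5*10 mm3 = 0.0625 mL exactly
        vol = make_suv_volume(vox, spacing=(2.5, 2.5, 10.0))
        seg = threshold_segment(vol, np.ones_like(vox, bool), 2.0)
        retained = {tuple(v) for v in np.argwhere(seg.mask)}
        expected = brute_force_threshold_segment(
            vox, np.ones_like(vox, bool), 2.0, vol.voxel_volume_ml)
        assert retained == expected
        assert len(seg.components) == 1
        assert seg.components[0][1] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed,connectivity", [(0, 26), (1, 26), (2, 6)])
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        vox = rng.uniform(0, 4, (14, 14, 14))
        voi = rng.random((14, 14, 14)) < 0.7
        vol = make_suv_volume(vox, spacing=(3, 3, 3))
        seg = threshold_segment(vol, voi, 2.0, min_component_ml=1.0,
                                connectivity=connectivity)
        retained = {tuple(v) for v in np.argwhere(seg.mask)}
        expected = brute_force_threshold_segment(
            vox, voi, 2.0, vol.voxel_volume_ml, 1.0, connectivity)
        assert retained == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        vox = rng.uniform(0, 4, (16, 16, 16))
        vol = make_suv_volume(vox)
        voi = np.ones_like(vox, bool)
        prev = None
        for thr in (0.5, 1.0, 1.5, 2.0, 3.0):
            seg = threshold_segment(vol, voi, thr, min_component_ml=0.0)
            if prev is not None:
                assert seg.volume_ml <= prev.volume_ml
                assert seg.suv_total <= prev.suv_total
            prev = seg

    def test_component_filter_superset(self):
        rng = np.random.default_rng(4)
        vox = rng.uniform(0, 4, (16, 16, 16))
        vol = make_suv_volume(vox)
        voi = np.ones_like(vox, bool)
        loose = threshold_segment(vol, voi, 2.5, min_component_ml=0.0)
        strict = threshold_segment(vol, voi, 2.5, min_component_ml=1.0)
        assert np.all(loose.mask >= strict.mask)

    def test_metric_ordering_invariant(self):
        rng = np.random.default_rng(5)
        vox = ndimage.gaussian_filter(rng.uniform(0, 6, (18, 18, 18)), 1.5)
        vol = make_suv_volume(vox)
        seg = threshold_segment(vol, np.ones_like(vox, bool), float(vox.mean()),
                                min_component_ml=1.0)
        if seg.volume_ml >= 1.0 and np.isfinite(seg.suv_peak):
            assert seg.suv_mean <= seg.suv_peak + 1e-12
            assert seg.suv_peak <= seg.suv_max + 1e-12
        assert seg.suv_total == pytest.approx(seg.suv_mean * seg.volume_ml, rel=1e-6)

    def test_nonpositive_threshold_rejected(self):
        vol = make_suv_volume(np.ones((6, 6, 6)))
        with pytest.raises(ValueError):
            threshold_segment(vol, np.ones((6, 6, 6), bool), 0.0)


def _sphere_phantom(diameter_mm, fwhm_mm, n=72, spacing=1.0,
                    hot=4.0, background=1.0):
    """Uniform hot sphere in warm background, Gaussian-blurred; returns
    (blurred volume, true mask)."""
    ax = (np.arange(n) - (n - 1) / 2.0) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    true_mask = X**2 + Y**2 + Z**2 <= (diameter_mm / 2.0) ** 2
    truth = np.where(true_mask, hot, background)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing
    blurred = ndimage.gaussian_filter(truth, sigma) if fwhm_mm > 0 else truth
    vol = make_suv_volume(blurred, spacing=(spacing,) * 3)
    return vol, true_mask


class TestPVC:
    def test_zero_fwhm_is_identity(self):
        vol, mask = _sphere_phantom(30, 0.0, n=48)
        seg = threshold_segment(vol, np.ones_like(mask), 2.0)
        c = pvc_correct(seg, vol, psf_fwhm_mm=0.0)
        assert c == pytest.approx(seg.suv_total, rel=1e-12)

    def test_large_sphere_recovery_within_5pct(self):
        vol, true_mask = _sphere_phantom(40, 6.0)
        seg = threshold_segment(vol, np.ones_like(true_mask), 2.0)
        assert seg.suv_mean < 4.0  # partial volume effect biases down
        pvc_correct(seg, vol, psf_fwhm_mm=6.0)
        corrected_mean = seg.c_suv_total / seg.volume_ml
        assert corrected_mean == pytest.approx(4.0, rel=0.05)

    def test_correction_never_worse_when_halved(self):
        for d in (40, 20):
            vol, true_mask = _sphere_phantom(d, 6.0)
            seg = threshold_segment(vol, np.ones_like(true_mask), 2.0)
            pvc_correct(seg, vol, psf_fwhm_mm=6.0)
            uncorr_err = abs(seg.suv_mean - 4.0)
            corr_err = abs(seg.c_suv_total / seg.volume_ml - 4.0)
            assert corr_err <= uncorr_err + 1e-9

    def test_unstable_retention_falls_back(self):
        # a tiny mask under heavy blur: retention below the floor
        vox = np.ones((30, 30, 30))
        vox[15, 15, 15] = 5.0
        vol = make_suv_volume(vox, spacing=(1, 1, 1))
        seg = threshold_segment(vol, np.ones_like(vox, bool), 2.0,
                                min_component_ml=0.0)
        with pytest.warns(UserWarning):
            c = pvc_correct(seg, vol, psf_fwhm_mm=25.0)
        assert seg.pvc_fallback
        assert c == pytest.approx(seg.suv_total)

    def test_empty_segmentation(self):
        vol = make_suv_volume(np.ones((8, 8, 8)))
        seg = threshold_segment(vol, np.ones((8, 8, 8), bool), 5.0)
        assert pvc_correct(seg, vol, 6.0) == 0.0


class TestPatientGraftUptake:
    def _seg(self, total):
        from graftquant import SegmentationResult
        return SegmentationResult(mask=np.zeros((1, 1, 1), bool),
                                  suv_total=total, c_suv_total=total * 1.1)

    def test_sides_sum(self):
        total, ctotal = patient_graft_uptake([self._seg(600.0), self._seg(578.0)])
        assert total == pytest.approx(1178.0)
        assert ctotal == pytest.approx(1178.0 * 1.1)

    def test_single_passthrough(self):
        total, _ = patient_graft_uptake([self._seg(42.0)])
        assert total == pytest.approx(42.0)

    def test_two_levels_two_sides(self):
        total, _ = patient_graft_uptake([self._seg(7.0)] * 4)
        assert total == pytest.approx(28.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            patient_graft_uptake([])
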