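import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vesseltrace import (
    PhantomSpec,
    StainSpec,
    classify_perfusion,
    depthwise_overlap,
    make_phantom,
    mip,
    overlap_metrics,
    snr,
    snr_profile,
)
from vesseltrace.evaluation import DepthROI, ROISet, build_roi_set


# --------------------------------------------------------------------------
# SNR
# --------------------------------------------------------------------------


class TestSNR:
    def test_ratio_of_means(self):
        vol = np.zeros((2, 4, 4))
        vol[0] = 200.0
        vol[1] = 20.0
        sig = np.zeros_like(vol, dtype=bool)
        sig[0] = True
        assert snr(vol, sig, ~sig) == pytest.approx(10.0)

    def test_equal_rois_give_unity(self, rng):
        vol = rng.random((3, 5, 5)) + 1.0
        half = np.zeros_like(vol, dtype=bool)
        half[:, :2] = True
        vol[half] = 7.0
        vol[~half] = 7.0
        assert snr(vol, half, ~half) == pytest.approx(1.0)

    def test_zero_background_rejected(self):
        vol = np.zeros((2, 2, 2))
        vol[0] = 5.0
        sig = np.zeros_like(vol, dtype=bool)
        sig[0] = True
        with pytest.raises(ValueError, match="background"):
            snr(vol, sig, ~sig)

    def test_disjointness_enforced(self):
        roi = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            DepthROI(0.0, roi, roi)

    def test_rendered_phantom_snr_near_ten(self):
        spec = PhantomSpec.from_shape((32, 64, 64), seed=6)
        stain = StainSpec(attenuation_um=math.inf, psf_sigma_um=0.0, noise_sd=2.0)
        ph = make_phantom(spec, stain)
        rois = build_roi_set(ph.mask, voxel_z_um=2.0, step_um=20.0, voxel_xy_um=0.65)
        prof = snr_profile(ph.intensity, rois, step_um=20.0,
                           max_depth_um=(ph.mask.shape[0] - 1) * 2.0)
        assert prof.values.mean() == pytest.approx(10.0, rel=0.05)


class TestSNRProfile:
    def _roi_set(self, shape, depths, voxel_z):
        rois = []
        for d in depths:
            zi = int(round(d / voxel_z))
            sig = np.zeros(shape, dtype=bool)
            bgd = np.zeros(shape, dtype=bool)
            sig[zi, :2] = True
            bgd[zi, 2:] = True
            rois.append(DepthROI(d, sig, bgd))
        return ROISet(rois)

    def test_bin_count_matches_sampling_plan(self):
        # 0..500 um inclusive at 20 um steps -> 26 bins
        shape = (251, 4, 4)
        vol = np.ones(shape)
        vol[:, :2] += 1.0
        depths = np.arange(0.0, 501.0, 20.0)
        roi_set = self._roi_set(shape, depths, voxel_z=2.0)
        prof = snr_profile(vol, roi_set, step_um=20.0, max_depth_um=500.0)
        assert len(prof.depths_um) == 26

    def test_missing_depth_omitted_with_warning(self):
        shape = (251, 4, 4)
        vol = np.ones(shape)
        vol[:, :2] += 1.0
        depths = [d for d in np.arange(0.0, 501.0, 20.0) if d != 100.0]
        roi_set = self._roi_set(shape, depths, voxel_z=2.0)
        with pytest.warns(UserWarning, match="100"):
            prof = snr_profile(vol, roi_set, step_um=20.0, max_depth_um=500.0)
        assert len(prof.depths_um) == 25
        assert 100.0 not in prof.depths_um

    def test_attenuation_free_profile_constant(self):
        spec = PhantomSpec.from_shape((48, 64, 64), seed=8)
        stain = StainSpec(attenuation_um=math.inf, psf_sigma_um=0.0, noise_sd=0.0)
        ph = make_phantom(spec, stain)
        rois = build_roi_set(ph.mask, voxel_z_um=2.0, step_um=20.0, voxel_xy_um=0.65)
        prof = snr_profile(ph.intensity, rois, step_um=20.0, max_depth_um=94.0)
        np.testing.assert_allclose(prof.values, prof.values[0], rtol=1e-6)

    def test_finite_attenuation_profile_matches_closed_form(self):
        lam = 250.0
        spec = PhantomSpec.from_shape((48, 64, 64), seed=8)
        stain = StainSpec(attenuation_um=lam, psf_sigma_um=0.0, noise_sd=0.0)
        ph = make_phantom(spec, stain)
        rois = build_roi_set(ph.mask, voxel_z_um=2.0, step_um=20.0, voxel_xy_um=0.65)
        prof = snr_profile(ph.intensity, rois, step_um=20.0, max_depth_um=94.0)
        zc = prof.depths_um + 0.5 * 2.0  # ROI slice centers
        expected = (20.0 + 180.0 * np.exp(-zc / lam)) / 20.0
        np.testing.assert_allclose(prof.values, expected, rtol=1e-6)


# --------------------------------------------------------------------------
# MIP
# --------------------------------------------------------------------------


class TestMIP:
    def test_forty_micron_slab_is_twenty_slices(self):
        vol = np.zeros((30, 2, 2))
        vol[19] = 1.0  # last slice inside the slab
        vol[20] = 2.0  # first slice outside
        out = mip(vol, z_start_um=0.0, thickness_um=40.0, voxel_z_um=2.0)
        assert out.max() == 1.0

    def test_single_slice_slab(self, rng):
        vol = rng.random((5, 3, 3))
        np.testing.assert_array_equal(mip(vol, 4.0, 2.0, 2.0), vol[2])

    def test_single_bright_voxel(self):
        vol = np.zeros((10, 8, 8))
        vol[4, 3, 5] = 9.0
        out = mip(vol, 0.0, 20.0, 2.0)
        assert out[3, 5] == 9.0 and out.sum() == 9.0

    def test_empty_slab_rejected(self):
        with pytest.raises(ValueError):
            mip(np.zeros((4, 2, 2)), z_start_um=100.0, thickness_um=40.0, voxel_z_um=2.0)


# --------------------------------------------------------------------------
# Overlap metrics
# --------------------------------------------------------------------------


class TestOverlap:
    def test_perfect_agreement(self, rng):
        m = rng.random((6, 6, 6)) < 0.3
        oc = overlap_metrics(m, m)
        assert (oc.tp_rate, oc.fp_rate, oc.fn_rate) == (100.0, 0.0, 0.0)
        assert oc.precision == oc.recall == 1.0

    def test_complement_masks(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        oc = overlap_metrics(~m, m)
        assert oc.tp == 0 and oc.precision == 0.0 and oc.recall == 0.0

    def test_printed_formula_example(self):
        from vesseltrace.evaluation import OverlapCounts

        oc = OverlapCounts(tp=90, fp=10, fn=10)
        assert oc.precision == pytest.approx(0.9)
        assert oc.recall == pytest.approx(0.9)

    def test_empty_reference_reports_missing_rates(self, rng):
        a = rng.random((4, 4, 4)) < 0.5
        oc = overlap_metrics(a, np.zeros((4, 4, 4), dtype=bool))
        assert oc.tp_rate is None and oc.fn_rate is None
        assert oc.fp_rate is not None  # |A| > 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=arrays(bool, (4, 5, 3), elements=st.booleans()),
        m=arrays(bool, (4, 5, 3), elements=st.booleans()),
    )
    def test_exact_count_conservation(self, a, m):
        oc = overlap_metrics(a, m)
        # brute-force counts via explicit iteration
        tp = fp = fn = 0
        for idx in np.ndindex(a.shape):
            tp += a[idx] and m[idx]
            fp += a[idx] and not m[idx]
            fn += m[idx] and not a[idx]
        assert (oc.tp, oc.fp, oc.fn) == (tp, fp, fn)
        assert oc.tp + oc.fn == int(m.sum())
        assert oc.tp + oc.fp == int(a.sum())
        if oc.n_reference:
            assert oc.recall == oc.tp_rate / 100.0
            assert oc.tp_rate + oc.fn_rate == pytest.approx(100.0)
        if oc.n_auto:
            assert 0.0 <= oc.precision <= 1.0


class TestDepthwise:
    def test_identical_volumes_give_full_tp_profile(self, rng):
        m = rng.random((40, 8, 8)) < 0.3
        counts, profiles = depthwise_overlap(m, m, slab_um=40.0, voxel_z_um=2.0)
        assert all(c.tp_rate == 100.0 for c in counts)
        np.testing.assert_allclose(profiles["tp_rate"].values, 100.0)

    def test_vessels_only_in_upper_half(self):
        ref = np.zeros((40, 8, 8), dtype=bool)
        ref[:, 2:4, 2:4] = True  # everywhere in z
        auto = ref.copy()
        auto[20:] = False  # missing below 40 um
        counts, _ = depthwise_overlap(auto, ref, slab_um=40.0, voxel_z_um=2.0)
        assert counts[0].fn_rate == 0.0
        assert counts[1].fn_rate == 100.0

    def test_too_thin_slab_rejected(self, rng):
        m = rng.random((10, 4, 4)) < 0.5
        with pytest.raises(ValueError, match="slab"):
            depthwise_overlap(m, m, slab_um=0.5, voxel_z_um=2.0)

    def test_voxelwise_and_mip_counts_differ(self, rng):
        ref = rng.random((20, 16, 16)) < 0.2
        auto = rng.random((20, 16, 16)) < 0.2
        c_mip, _ = depthwise_overlap(auto, ref, slab_um=40.0, voxel_z_um=2.0, on_mips=True)
        c_vox, _ = depthwise_overlap(auto, ref, slab_um=40.0, voxel_z_um=2.0, on_mips=False)
        assert c_vox[0].n_reference == int(ref.sum())
        assert c_mip[0].n_reference == int(ref.max(axis=0).sum())


# --------------------------------------------------------------------------
# Perfusion classification
# --------------------------------------------------------------------------


class TestPerfusion:
    @pytest.mark.parametrize(
        "length,stained,perfused",
        [
            (100.0, 100.0, True),  # fully stained
            (100.0, 49.0, False),  # unstained fraction 0.51 > 0.5
            (100.0, 50.0, True),  # boundary: exactly half unstained stays perfused
            (100.0, 51.0, True),
        ],
    )
    def test_half_length_rule(self, length, stained, perfused):
        flags, _ = classify_perfusion([(length, stained)])
        assert flags[0] is perfused

    def test_percentage_of_perfused_branches(self):
        branches = [(10.0, 10.0), (10.0, 2.0), (10.0, 8.0), (10.0, 0.0)]
        _, pct = classify_perfusion(branches)
        assert pct == pytest.approx(50.0)

    def test_zero_length_branch_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            classify_perfusion([(0.0, 0.0)])

    def test_stained_longer_than_branch_rejected(self):
        with pytest.raises(ValueError):
            classify_perfusion([(10.0, 11.0)])
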