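import itertools
import math

import numpy as np
import pytest
from scipy import ndimage

from vesseltrace import HMRFConfig, MRFModel, hmrf_segment, segment_blockwise, threshold_segment
from vesseltrace.segmentation import (
    estimate_params,
    icm_optimize,
    icm_sweep,
    init_labels,
    mrf_energy,
)

from conftest import assert_non_increasing


# --------------------------------------------------------------------------
# Independent brute-force oracle (kept deliberately naive)
# --------------------------------------------------------------------------


def brute_energy(volume, labels, mu, var, beta):
    """Reference energy by explicit per-voxel and per-pair loops."""
    e = 0.0
    shape = volume.shape
    for idx in np.ndindex(shape):
        l = int(labels[idx])
        e += (volume[idx] - mu[l]) ** 2 / (2 * var[l]) + 0.5 * math.log(2 * math.pi * var[l])
    for idx in np.ndindex(shape):
        for ax in range(3):
            nb = list(idx)
            nb[ax] += 1
            if nb[ax] < shape[ax]:
                e += beta * (labels[idx] != labels[tuple(nb)])
    return e


def brute_map(volume, mu, var, beta):
    """Exhaustive MAP labeling over all 2^n configurations."""
    shape = volume.shape
    n = volume.size
    best, best_e = None, np.inf
    for bits in itertools.product((0, 1), repeat=n):
        lab = np.asarray(bits, dtype=np.uint8).reshape(shape)
        e = brute_energy(volume, lab, mu, var, beta)
        if e < best_e:
            best, best_e = lab, e
    return best, best_e


# --------------------------------------------------------------------------
# Initialization
# --------------------------------------------------------------------------


class TestInitLabels:
    def test_separable_two_value_volume(self, rng):
        vol = np.full((10, 10, 10), 10.0)
        hot = rng.random((10, 10, 10)) < 0.1
        vol[hot] = 200.0
        for method in ("otsu", "kmeans2"):
            labels = init_labels(vol, method)
            np.testing.assert_array_equal(labels.astype(bool), hot)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            init_labels(np.full((4, 4, 4), 7.0))

    def test_well_separated_mixture_misassignment(self, rng):
        # means 6 sd apart: Bayes error is ~1e-9, so <1% misassignment
        truth = rng.random(10**5) < 0.3
        vol = np.where(truth, rng.normal(150, 10, 10**5), rng.normal(30, 10, 10**5))
        labels = init_labels(vol.reshape(100, 100, 10), "otsu").ravel().astype(bool)
        assert (labels != truth).mean() < 0.01


# --------------------------------------------------------------------------
# Energy
# --------------------------------------------------------------------------


class TestEnergy:
    def test_matches_brute_force_on_all_labelings(self):
        vol = np.array([[[0.0, 0.0], [100.0, 100.0]]]).reshape(2, 2, 1)
        model = MRFModel(0.0, 100.0, 50.0, 50.0, beta=1.0)
        for bits in itertools.product((0, 1), repeat=4):
            lab = np.asarray(bits, dtype=np.uint8).reshape(2, 2, 1)
            expected = brute_energy(vol, lab, (0.0, 100.0), (50.0, 50.0), 1.0)
            assert mrf_energy(vol, lab, model) == pytest.approx(expected)

    def test_uniform_labels_have_no_pairwise_term(self, rng):
        vol = rng.normal(size=(4, 5, 6))
        model = MRFModel(-1.0, 1.0, 1.0, 1.0, beta=3.0)
        lab = np.zeros(vol.shape, dtype=np.uint8)
        model0 = MRFModel(-1.0, 1.0, 1.0, 1.0, beta=0.0)
        assert mrf_energy(vol, lab, model) == pytest.approx(mrf_energy(vol, lab, model0))

    def test_beta_zero_minimized_by_pointwise_ml(self, rng):
        vol = rng.normal(size=(5, 5, 5))
        model = MRFModel(-1.0, 1.0, 1.0, 1.0, beta=0.0)
        d0 = (vol + 1.0) ** 2 / 2 + 0.5 * math.log(2 * math.pi)
        d1 = (vol - 1.0) ** 2 / 2 + 0.5 * math.log(2 * math.pi)
        ml = (d1 < d0).astype(np.uint8)
        assert mrf_energy(vol, ml, model) == pytest.approx(np.minimum(d0, d1).sum())

    def test_variance_floor_enforced(self):
        with pytest.raises(ValueError, match="floor"):
            MRFModel(0.0, 1.0, 0.0, 1.0)


# --------------------------------------------------------------------------
# ICM
# --------------------------------------------------------------------------


class TestICM:
    def test_descent_on_random_instances(self, rng):
        model = MRFModel(0.0, 1.0, 0.25, 0.25, beta=0.7)
        for _ in range(20):
            vol = rng.normal(0.5, 1.0, size=(4, 4, 4))
            lab = (rng.random(vol.shape) < 0.5).astype(np.uint8)
            e0 = mrf_energy(vol, lab, model)
            lab1 = icm_sweep(vol, lab, model)
            e1 = mrf_energy(vol, lab1, model)
            assert e1 <= e0 + 1e-9

    def test_local_minimum_is_fixed_point(self, rng):
        model = MRFModel(0.0, 1.0, 0.25, 0.25, beta=0.5)
        vol = rng.normal(0.5, 1.0, size=(4, 4, 4))
        lab = icm_optimize(vol, (vol > 0.5).astype(np.uint8), model)
        np.testing.assert_array_equal(icm_sweep(vol, lab, model), lab)

    def test_reaches_enumerated_map_on_separated_image(self):
        vol = np.array([[10.0, 10.0, 200.0], [10.0, 10.0, 200.0], [10.0, 200.0, 200.0]])
        vol = vol.reshape(3, 3, 1)
        model = MRFModel(10.0, 200.0, 100.0, 100.0, beta=1.0)
        lab = icm_optimize(vol, init_labels(vol, "otsu"), model)
        map_lab, map_e = brute_map(vol, (10.0, 200.0), (100.0, 100.0), 1.0)
        assert mrf_energy(vol, lab, model) == pytest.approx(map_e)
        np.testing.assert_array_equal(lab, map_lab)


# --------------------------------------------------------------------------
# Parameter estimation
# --------------------------------------------------------------------------


class TestEstimateParams:
    def test_exact_on_noise_free_two_value_volume(self):
        vol = np.full((6, 6, 6), 10.0)
        vol[2:4] = 200.0
        lab = (vol > 100).astype(np.uint8)
        mu0, mu1, var0, var1 = estimate_params(vol, lab)
        assert (mu0, mu1) == (10.0, 200.0)
        assert var0 == var1 == pytest.approx(1e-6)

    def test_single_class_labeling_warns_and_keeps_previous(self, rng):
        vol = rng.normal(size=(4, 4, 4))
        prev = MRFModel(-2.0, 2.0, 1.0, 1.5)
        with pytest.warns(UserWarning, match="empty"):
            mu0, mu1, var0, var1 = estimate_params(vol, np.zeros_like(vol, dtype=np.uint8), prev)
        assert (mu1, var1) == (2.0, 1.5)

    def test_gaussian_classes_recovered_within_standard_error(self, rng):
        n = 50_000
        truth = rng.random(n) < 0.4
        vol = np.where(truth, rng.normal(150, 10, n), rng.normal(30, 10, n)).reshape(50, 100, 10)
        mu0, mu1, var0, var1 = estimate_params(vol, truth.reshape(vol.shape).astype(np.uint8))
        se = 10 / math.sqrt(n * 0.4)
        assert abs(mu1 - 150) < 3 * se
        assert abs(mu0 - 30) < 3 * se * math.sqrt(0.4 / 0.6)


# --------------------------------------------------------------------------
# Full segmenters
# --------------------------------------------------------------------------


class TestHMRF:
    def test_noise_free_two_region_volume_recovered_exactly(self):
        vol = np.full((8, 8, 8), 10.0)
        vol[:, :4] = 200.0
        res = hmrf_segment(vol)
        np.testing.assert_array_equal(res.labels.astype(bool), vol > 100)
        assert_non_increasing(res.energy_trace)

    def test_beta_zero_equals_pointwise_ml(self, rng):
        vol = np.where(rng.random((12, 12, 12)) < 0.2,
                       rng.normal(150, 15, (12, 12, 12)),
                       rng.normal(30, 15, (12, 12, 12)))
        res = hmrf_segment(vol, HMRFConfig(beta=0.0))
        m = res.model
        z = (vol - res.norm_mean) / res.norm_sd
        d0 = (z - m.mu0) ** 2 / (2 * m.var0) + 0.5 * np.log(2 * np.pi * m.var0)
        d1 = (z - m.mu1) ** 2 / (2 * m.var1) + 0.5 * np.log(2 * np.pi * m.var1)
        np.testing.assert_array_equal(res.labels, (d1 < d0).astype(np.uint8))
        assert_non_increasing(res.energy_trace)

    def test_labels_invariant_to_intensity_shift(self, rng):
        vol = np.where(rng.random((10, 10, 10)) < 0.3,
                       rng.normal(150, 20, (10, 10, 10)),
                       rng.normal(30, 20, (10, 10, 10)))
        a = hmrf_segment(vol)
        b = hmrf_segment(vol + 1000.0)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_energy_descent_on_phantom(self, small_lumen_phantom):
        res = hmrf_segment(small_lumen_phantom.intensity)
        assert_non_increasing(res.energy_trace)
        assert res.converged

    def test_accuracy_on_lumen_phantom(self, small_lumen_phantom):
        # SNR-10 lumen staining: voxelwise agreement with truth above 95%
        res = hmrf_segment(small_lumen_phantom.intensity)
        acc = (res.labels.astype(bool) == small_lumen_phantom.mask).mean()
        assert acc > 0.95

    def test_smoothing_reduces_isolated_foreground_voxels(self, small_lumen_phantom):
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        counts = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            res = hmrf_segment(small_lumen_phantom.intensity, HMRFConfig(beta=beta))
            lab, n = ndimage.label(res.labels, structure=structure)
            sizes = np.bincount(lab.ravel())[1:]
            counts.append(int((sizes == 1).sum()))
        assert all(b <= a for a, b in zip(counts[:-1], counts[1:]))

    def test_degenerate_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hmrf_segment(np.full((4, 4, 4), 3.0))

    def test_non_finite_volume_rejected(self):
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            hmrf_segment(vol)


class TestThresholdBaselines:
    def test_two_value_volume_equals_hmrf(self, rng):
        vol = np.full((8, 8, 8), 10.0)
        vol[rng.random((8, 8, 8)) < 0.2] = 200.0
        hm = hmrf_segment(vol).labels
        for method in ("otsu", "isodata", "mean"):
            np.testing.assert_array_equal(threshold_segment(vol, method), hm)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            threshold_segment(rng.random((4, 4, 4)), "magic")

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            threshold_segment(np.ones((4, 4, 4)), "otsu")

    def test_thresholding_misses_more_deep_wall_signal_than_mrf(self, small_wall_phantom):
        # attenuated wall staining: global Otsu loses the dim deep walls
        from vesseltrace import depthwise_overlap

        ph = small_wall_phantom
        mrf = hmrf_segment(ph.intensity).labels.astype(bool)
        otsu = threshold_segment(ph.intensity, "otsu").astype(bool)
        kw = dict(slab_um=40.0, voxel_z_um=ph.spec.voxel_um[0], on_mips=True)
        _, prof_mrf = depthwise_overlap(mrf, ph.mask, **kw)
        _, prof_otsu = depthwise_overlap(otsu, ph.mask, **kw)
        assert prof_otsu["fn_rate"].values[-1] > prof_mrf["fn_rate"].values[-1]


class TestBlockwise:
    def test_matches_whole_volume_on_phantom(self, small_lumen_phantom):
        vol = small_lumen_phantom.intensity
        whole = hmrf_segment(vol)
        block = segment_blockwise(vol, block_shape=(24, 48, 48), halo=6)
        agreement = (whole.labels == block.labels).mean()
        assert agreement >= 0.99

    def test_zero_halo_rejected(self, rng):
        with pytest.raises(ValueError, match="halo"):
            segment_blockwise(rng.random((8, 8, 8)), halo=0)

    def test_block_smaller_than_twice_halo_rejected(self, rng):
        with pytest.raises(ValueError, match="block"):
            segment_blockwise(rng.random((32, 32, 32)), block_shape=(4, 32, 32), halo=4)

    def test_single_block_equals_whole_volume(self):
        vol = np.full((16, 16, 16), 10.0)
        vol[4:12, 4:12, 4:12] = 200.0
        whole = hmrf_segment(vol)
        single = segment_blockwise(vol, block_shape=(16, 16, 16), halo=2)
        np.testing.assert_array_equal(whole.labels, single.labels)
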