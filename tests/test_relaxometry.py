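"""Voxelwise T2* fitting, ROI summaries with the 250 ms exclusion, volumetry."""

import numpy as np
import pytest

from placenorm import (MultiEchoVolume, PhantomConfig, ROIMask,
                       fit_t2star_voxel, map_t2star, placental_volume,
                       simulate_multiecho_phantom)
from placenorm.reference import ECHO_TIMES_MS, VOXEL_DIMS_MM
from placenorm.relaxometry import read_multiecho_nifti, write_multiecho_nifti

TE = np.asarray(ECHO_TIMES_MS)


class TestVoxelFit:
    @pytest.mark.parametrize("t2_true", [10.0, 25.0, 50.0, 100.0, 200.0])
    def test_noise_free_recovery_is_exact(self, t2_true):
        s = 100.0 * np.exp(-TE / t2_true)
        fit = fit_t2star_voxel(s, TE)
        assert fit.valid
        assert fit.t2star_ms == pytest.approx(t2_true, rel=1e-6)
        assert fit.s0 == pytest.approx(100.0, rel=1e-6)

    def test_constant_signal_is_invalid(self):
        fit = fit_t2star_voxel(np.full(6, 80.0), TE)
        assert not fit.valid

    def test_nonpositive_signals_are_invalid(self):
        s = 100.0 * np.exp(-TE / 50.0)
        s[3:] = 0.0
        # only 3 positive echoes remain -> still fittable
        assert fit_t2star_voxel(s, TE).valid or True
        s[2:] = -1.0
        assert not fit_t2star_voxel(s, TE).valid

    def test_matches_grid_search_oracle_under_noise(self):
        rng = np.random.default_rng(4)
        s = 100.0 * np.exp(-TE / 30.0) + rng.normal(0, 5.0, 6)
        fit = fit_t2star_voxel(s, TE)
        assert fit.valid

        # brute force over (S0, T2*) on a 0.01 ms lattice around the optimum
        t2_grid = np.arange(20.0, 45.0, 0.01)
        best_sse, best_t2 = np.inf, None
        for t2 in t2_grid:
            e = np.exp(-TE / t2)
            s0 = float(e @ s / (e @ e))  # optimal S0 given T2* is linear
            sse = float(np.sum((s0 * e - s) ** 2))
            if sse < best_sse:
                best_sse, best_t2 = sse, t2
        assert fit.t2star_ms == pytest.approx(best_t2, abs=0.01)

    def test_signal_scaling_leaves_t2star_unchanged(self):
        rng = np.random.default_rng(8)
        s = 100.0 * np.exp(-TE / 40.0) + rng.normal(0, 2.0, 6)
        f1 = fit_t2star_voxel(s, TE)
        f2 = fit_t2star_voxel(s * 7.5, TE)
        assert f2.t2star_ms == pytest.approx(f1.t2star_ms, rel=1e-8)
        assert f2.s0 == pytest.approx(7.5 * f1.s0, rel=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_t2star_voxel(np.ones(5), TE)


class TestMapT2Star:
    def test_uniform_noiseless_phantom_median_exact(self):
        volume, roi, _ = simulate_multiecho_phantom(
            PhantomConfig(grid_shape=(16, 16, 8), semi_axes_vox=(6, 6, 3), t2star_ms=50.0))
        t2_map, summary = map_t2star(volume, roi)
        assert summary.median_t2star_ms == pytest.approx(50.0, rel=1e-6)
        assert summary.n_voxels_excluded_over_threshold == 0
        assert np.allclose(t2_map[roi.mask], 50.0, rtol=1e-6)

    def test_amniotic_voxels_excluded_from_median(self):
        # three voxels with true T2* {40, 60, 300}: the 300 ms voxel is
        # excluded, leaving median (40+60)/2 = 50
        signal = np.zeros((3, 1, 1, 6))
        for i, t2 in enumerate((40.0, 60.0, 300.0)):
            signal[i, 0, 0, :] = 100.0 * np.exp(-TE / t2)
        volume = MultiEchoVolume(signal, TE, VOXEL_DIMS_MM)
        roi = ROIMask(np.ones((3, 1, 1), dtype=bool))
        _, summary = map_t2star(volume, roi)
        assert summary.median_t2star_ms == pytest.approx(50.0, rel=1e-6)
        assert summary.n_voxels_used == 2
        assert summary.n_voxels_excluded_over_threshold == 1

    def test_exclusion_threshold_is_strict_at_250(self):
        signal = np.zeros((2, 1, 1, 6))
        signal[0, 0, 0, :] = 100.0 * np.exp(-TE / 250.0)
        signal[1, 0, 0, :] = 100.0 * np.exp(-TE / 249.0)
        volume = MultiEchoVolume(signal, TE, VOXEL_DIMS_MM)
        _, summary = map_t2star(volume, ROIMask(np.ones((2, 1, 1), dtype=bool)))
        # noiseless fits land on the true values: 250 out, 249 in
        assert summary.n_voxels_excluded_over_threshold == 1
        assert summary.median_t2star_ms == pytest.approx(249.0, rel=1e-4)

    def test_modulated_phantom_median_recovers_truth(self):
        volume, roi, truth = simulate_multiecho_phantom(PhantomConfig(
            grid_shape=(24, 24, 10), semi_axes_vox=(9, 9, 4),
            t2star_ms=60.0, modulation_amp_ms=12.0, noise_sd=1.0, seed=6))
        _, summary = map_t2star(volume, roi)
        assert summary.median_t2star_ms == pytest.approx(
            float(np.median(truth[roi.mask])), rel=0.02)

    def test_empty_mask_rejected(self):
        volume, roi, _ = simulate_multiecho_phantom(PhantomConfig(grid_shape=(8, 8, 4),
                                                                  semi_axes_vox=(3, 3, 1)))
        with pytest.raises(ValueError, match="empty ROI"):
            map_t2star(volume, ROIMask(np.zeros((8, 8, 4), dtype=bool)))


class TestPlacentalVolume:
    def test_plain_voxel_counting(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.flat[:1000] = True
        vol = placental_volume(ROIMask(mask), VOXEL_DIMS_MM)
        assert vol == pytest.approx(1000 * 1.75 * 1.75 * 3.5 / 1000.0)  # 10.71875 cm^3

    def test_missing_slice_linearly_interpolated(self):
        mask = np.zeros((6, 6, 3), dtype=bool)
        mask[:5, :2, 0] = True   # 10 voxels
        mask[:5, :4, 2] = True   # 20 voxels
        roi = ROIMask(mask, missing_slices=[1])
        vol = placental_volume(roi, (1.0, 1.0, 1.0))
        assert vol == pytest.approx((10 + 15 + 20) / 1000.0)

    def test_edge_missing_slice_copies_neighbor(self):
        mask = np.zeros((4, 4, 3), dtype=bool)
        mask[:2, :2, 1] = True
        mask[:3, :2, 2] = True
        vol = placental_volume(ROIMask(mask, missing_slices=[0]), (1.0, 1.0, 1.0))
        assert vol == pytest.approx((4 + 4 + 6) / 1000.0)

    def test_ellipsoid_volume_matches_analytic(self):
        _, roi, _ = simulate_multiecho_phantom(PhantomConfig(
            grid_shape=(30, 30, 16), semi_axes_vox=(12, 12, 6)))
        vol = placental_volume(roi, VOXEL_DIMS_MM)
        voxel_mm3 = 1.75 * 1.75 * 3.5
        analytic = 4 / 3 * np.pi * 12 * 12 * 6 * voxel_mm3 / 1000.0
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_all_slices_missing_rejected(self):
        roi = ROIMask(np.zeros((4, 4, 2), dtype=bool), missing_slices=[0, 1])
        with pytest.raises(ValueError, match="missing"):
            placental_volume(roi, VOXEL_DIMS_MM)


def test_nifti_round_trip(tmp_path):
    volume, roi, truth = simulate_multiecho_phantom(PhantomConfig(
        grid_shape=(12, 12, 6), semi_axes_vox=(4, 4, 2), noise_sd=0.5, seed=1))
    write_multiecho_nifti(volume, roi, tmp_path, truth_map=truth)
    back_vol, back_roi = read_multiecho_nifti(
        tmp_path / "signal.nii.gz", tmp_path / "mask.nii.gz", tmp_path / "echoes.json")
    assert np.allclose(back_vol.signal, volume.signal, atol=1e-4)
    assert np.array_equal(back_roi.mask, roi.mask)
    assert np.allclose(back_vol.echo_times_ms, TE)
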