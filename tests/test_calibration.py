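import numpy as np
import pytest

from _oracles import subpixel_shift_pe

from msnd import (
    FatSpectrum,
    FieldContext,
    WaterFatImage,
    autocalibrate_csm,
    calibrate_csm_b0,
    cpr_correct,
    default_trajectory,
    estimate_b0_water_fat,
    make_masks,
    make_phantom,
    nrmse,
    simulate_acquisition,
)
from msnd.calibration import _b0_distort, csm_alignment_error
from msnd.linalg import ifft2c


class TestMakeMasks:
    def test_all_zero_image_gives_empty_masks(self):
        wm, fm = make_masks(WaterFatImage(np.zeros((16, 16)), np.zeros((16, 16))))
        assert not wm.any() and not fm.any()

    def test_disk_mask_matches_brute_force_morphology(self):
        # independent oracle: hand-rolled erosion/dilation with the 3x3 cross
        grid = (64, 64)
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 < 10**2).astype(float)
        wm, _ = make_masks(WaterFatImage(disk, np.zeros(grid)), 0.03, 1, 3)

        def brute_erode(m):
            out = np.zeros_like(m, dtype=bool)
            for y in range(64):
                for x in range(64):
                    vals = [m[y, x]]
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        yy2, xx2 = y + dy, x + dx
                        vals.append(
                            m[yy2, xx2] if 0 <= yy2 < 64 and 0 <= xx2 < 64 else False
                        )
                    out[y, x] = all(vals)
            return out

        def brute_dilate(m):
            out = np.zeros_like(m, dtype=bool)
            for y in range(64):
                for x in range(64):
                    vals = [m[y, x]]
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        yy2, xx2 = y + dy, x + dx
                        vals.append(
                            m[yy2, xx2] if 0 <= yy2 < 64 and 0 <= xx2 < 64 else False
                        )
                    out[y, x] = any(vals)
            return out

        ref = disk > 0.03
        ref = brute_erode(ref)
        for _ in range(3):
            ref = brute_dilate(ref)
        np.testing.assert_array_equal(wm.astype(bool), ref)

    def test_threshold_relative_to_maximum(self):
        img = np.zeros((16, 16))
        img[4:12, 4:12] = 10.0
        img[0, 0] = 0.2  # 2% of max: below the 3% default threshold
        wm, _ = make_masks(WaterFatImage(img, np.zeros((16, 16))))
        assert wm[0, 0] == 0.0
        assert wm[8, 8] == 1.0


class TestEstimateB0:
    def test_zero_field_recovered_to_sub_hertz(self, spectrum):
        truth = make_phantom(grid=(48, 48), num_shots=4, b0_range_hz=0.0, seed=30)
        traj = default_trajectory((48, 48), num_shots=4)
        s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        ctx = FieldContext(b0_map=np.zeros((48, 48)), csm=truth.csm)
        psi, _ = estimate_b0_water_fat(s0, ctx, traj, spectrum)
        assert np.abs(psi[truth.support()]).max() < 1.0

    def test_smooth_field_recovered_with_water_fat(self, spectrum):
        truth = make_phantom(grid=(64, 64), num_shots=4, b0_range_hz=150.0, seed=2)
        traj = default_trajectory((64, 64), num_shots=4)
        s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        ctx = FieldContext(b0_map=np.zeros((64, 64)), csm=truth.csm)
        psi, wf = estimate_b0_water_fat(s0, ctx, traj, spectrum)
        support = truth.support()
        rmse = np.sqrt(np.mean((psi - truth.b0_map)[support] ** 2))
        assert rmse < 5.0
        assert nrmse(np.abs(wf.water), np.abs(truth.water)) < 0.02
        assert nrmse(np.abs(wf.fat), np.abs(truth.fat)) < 0.02

    def test_swap_initialization_converges_to_swapped_solution(self):
        # initializing at the water/fat ambiguity traps the Gauss-Newton in
        # the swapped local minimum on a fat-only object (known hazard)
        spec1 = FatSpectrum.single_peak(-434.3, 3.0)
        truth = make_phantom(grid=(48, 48), num_shots=4, b0_range_hz=0.0, seed=31)
        fat_only = make_phantom(grid=(48, 48), num_shots=4, b0_range_hz=0.0, seed=31)
        fat_only.fat = truth.water.copy()  # fat occupies the body interior
        fat_only.water = np.zeros_like(truth.water)
        traj = default_trajectory((48, 48), num_shots=4)
        s0 = simulate_acquisition(fat_only, traj, spec1, bvalue=0.0, noise_sigma=0.0)
        ctx = FieldContext(b0_map=np.zeros((48, 48)), csm=fat_only.csm)
        psi_swap = np.full((48, 48), -434.3)
        psi, wf = estimate_b0_water_fat(
            s0, ctx, traj, spec1, psi_init=psi_swap, grid_search=False
        )
        support = np.abs(fat_only.fat) > 0.1
        water_energy = np.linalg.norm(wf.water[support])
        fat_energy = np.linalg.norm(wf.fat[support])
        assert water_energy > fat_energy  # swapped: signal landed in water
        assert np.abs(psi[support] + 434.3).mean() < 60.0

    def test_requires_three_encodings(self, spectrum):
        truth = make_phantom(grid=(32, 32), num_shots=2, num_encodings=2, seed=32)
        traj = default_trajectory((32, 32), num_shots=2, delta_te=(0.2e-3, 1.0e-3))
        s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        ctx = FieldContext(b0_map=np.zeros((32, 32)), csm=truth.csm)
        with pytest.raises(ValueError):
            estimate_b0_water_fat(s0, ctx, traj, spectrum)


class TestDistortionCorrection:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(61)
        grid = (32, 32)
        traj = default_trajectory(grid, num_shots=4)
        img = rng.standard_normal(grid) + 1j * rng.standard_normal(grid)
        zero = np.zeros(grid)
        np.testing.assert_allclose(cpr_correct(img, zero, traj), img, atol=1e-10)
        np.testing.assert_allclose(
            calibrate_csm_b0(img[None], zero, traj)[0], img, atol=1e-10
        )

    def test_constant_field_shifts_by_shift_theorem(self):
        grid = (64, 64)
        traj = default_trajectory(grid, num_shots=4)
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        blob = np.exp(-((yy - 30) ** 2 + (xx - 28) ** 2) / 8.0).astype(complex)
        b0 = np.full(grid, 110.0)
        shifted = calibrate_csm_b0(blob[None], b0, traj)[0]
        predicted = 110.0 * traj.effective_dwell * 64
        assert abs(subpixel_shift_pe(shifted, blob) - predicted) < 0.05

    def test_cpr_restores_constant_field_displacement(self):
        grid = (64, 64)
        traj = default_trajectory(grid, num_shots=4)
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        blob = np.exp(-((yy - 30) ** 2 + (xx - 28) ** 2) / 8.0).astype(complex)
        b0 = np.full(grid, 110.0)
        displaced = _b0_distort(blob, b0, traj)
        restored = cpr_correct(displaced, b0, traj)
        assert abs(subpixel_shift_pe(restored, blob)) < 0.5

    def test_distort_and_cpr_are_approximate_inverses(self, spectrum):
        # smooth coil maps, moderate (+-50 Hz) field: round trip within 2%
        truth = make_phantom(grid=(64, 64), b0_range_hz=50.0, seed=3)
        traj = default_trajectory((64, 64), num_shots=4)
        support = truth.support()
        d = calibrate_csm_b0(truth.csm, truth.b0_map, traj)
        back = np.stack(
            [cpr_correct(d[j], truth.b0_map, traj) for j in range(d.shape[0])]
        )
        err = np.linalg.norm((back - truth.csm)[:, support]) / np.linalg.norm(
            truth.csm[:, support]
        )
        assert err < 0.02

    def test_smooth_field_residual_displacement_below_half_pixel(self, spectrum):
        # realistic-mode point source under a smooth field: CPR moves it back
        # to its true location
        grid = (64, 64)
        traj = default_trajectory(grid, num_shots=4)
        truth = make_phantom(
            grid=grid, num_shots=4, fat_fraction_layout="none",
            b0_range_hz=0.0, phase_amplitude_rad=0.0, seed=33,
        )
        yy, xx = np.meshgrid(np.linspace(-1, 1, 64), np.linspace(-1, 1, 64), indexing="ij")
        truth.b0_map[:] = 60.0 + 40.0 * yy  # smooth, nonzero at the source
        truth.water[:] = 0.0
        truth.water[30, 28] = 1.0
        truth.adc_map[:] = 0.0
        s = simulate_acquisition(
            truth, traj, spectrum, mode="realistic", bvalue=0.0, noise_sigma=0.0
        )
        img = np.sum(np.conj(truth.csm) * ifft2c(s.data[0].sum(axis=0)), axis=0)
        corrected = cpr_correct(img, truth.b0_map, traj)
        ref = np.sum(np.abs(truth.csm) ** 2, axis=0) * truth.water
        assert abs(subpixel_shift_pe(corrected, ref)) < 0.5


class TestAutocalibrateCsm:
    def test_single_uniform_coil_gives_unit_sensitivity(self, spectrum):
        truth = make_phantom(
            grid=(32, 32), num_shots=2, num_coils=1, fat_fraction_layout="none",
            b0_range_hz=0.0, seed=34,
        )
        truth.csm[:] = 1.0
        traj = default_trajectory((32, 32), num_shots=2)
        s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        csm = autocalibrate_csm(s0, traj, spectrum, np.zeros((32, 32)))
        support = truth.support()
        np.testing.assert_allclose(np.abs(csm[0][support]), 1.0, atol=1e-6)

    def test_recovers_smooth_maps_without_fat_or_field(self, spectrum):
        truth = make_phantom(
            grid=(64, 64), num_shots=4, fat_fraction_layout="none",
            b0_range_hz=0.0, seed=5,
        )
        traj = default_trajectory((64, 64), num_shots=4)
        s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        est = autocalibrate_csm(s0, traj, spectrum, np.zeros((64, 64)))
        rss = np.sqrt(np.sum(np.abs(truth.csm) ** 2, axis=0))
        ref = truth.csm / np.maximum(rss, 1e-12)
        assert csm_alignment_error(est, ref, truth.support()) < 0.05

    def test_fat_position_correction_improves_calibration(self, spectrum):
        # skipping the water/fat separation step (naive smoothed ratio of a
        # single encoding) leaves displaced-fat contamination in the maps
        from scipy import ndimage

        truth = make_phantom(grid=(64, 64), num_shots=4, b0_range_hz=100.0, seed=6)
        traj = default_trajectory((64, 64), num_shots=4)
        s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        support = truth.support()
        rss = np.sqrt(np.sum(np.abs(truth.csm) ** 2, axis=0))
        ref = truth.csm / np.maximum(rss, 1e-12)
        corrected = autocalibrate_csm(s0, traj, spectrum, truth.b0_map)
        naive_imgs = ifft2c(s0.data[0].sum(axis=1))
        sm = ndimage.gaussian_filter(naive_imgs.real, (0, 3, 3)) + 1j * ndimage.gaussian_filter(
            naive_imgs.imag, (0, 3, 3)
        )
        r = np.sqrt(np.sum(np.abs(sm) ** 2, axis=0))
        naive = np.where(r > 1e-3 * r.max(), sm / np.maximum(r, 1e-12), 0)
        err_corr = csm_alignment_error(corrected, ref, support)
        err_naive = csm_alignment_error(naive, ref, support)
        assert err_naive >= 2.0 * err_corr
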