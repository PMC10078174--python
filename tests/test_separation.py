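import numpy as np
import pytest

from _oracles import dense_forward_matrix, dense_muse_matrix

from msnd import (
    ChemShiftEncodedKSpace,
    FieldContext,
    ShotPhaseMaps,
    WaterFatImage,
    default_trajectory,
    init_diffusion_phase,
    make_phantom,
    merged_phase,
    nrmse,
    simulate_acquisition,
    solve_water_fat,
    water_fat_muse,
)
from msnd.encoding import EncodingSystem, EPITrajectory
from msnd.separation import ShotWaterFat
from msnd.simulator import attenuated_truth


class TestSolveWaterFat:
    def test_matches_dense_pseudo_inverse_on_small_system(self, small_system):
        b = small_system
        A = dense_forward_matrix(
            b["traj"], b["spectrum"], b["ctx"].csm, b["ctx"].csm,
            b["ctx"].b0_map, b["phases"].phases,
        )
        rng = np.random.default_rng(21)
        x_true = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        data = (A @ x_true).reshape(3, 2, 2, 8, 8)
        s = ChemShiftEncodedKSpace(data, b["traj"])
        wf, res = solve_water_fat(
            s, b["ctx"], b["phases"], b["traj"], b["spectrum"],
            cg_tol=1e-12, cg_maxiter=500,
        )
        want = (np.linalg.pinv(A) @ data.ravel()).reshape(2, 8, 8)
        got = np.stack([wf.water, wf.fat])
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-6

    def test_noiseless_recovery_on_phantom(self, spectrum):
        truth = make_phantom(grid=(48, 48), num_shots=4, seed=12)
        traj = default_trajectory((48, 48), num_shots=4)
        s = simulate_acquisition(truth, traj, spectrum, bvalue=600.0, noise_sigma=0.0)
        wf, _ = solve_water_fat(
            s, truth.field_context(), truth.true_phases[600.0], traj, spectrum,
            cg_tol=1e-8, cg_maxiter=200,
        )
        x = attenuated_truth(truth, 600.0)
        assert nrmse(wf.water, x.water) < 1e-4
        assert nrmse(wf.fat, x.fat) < 1e-4

    def test_zero_fat_truth_reconstructs_zero_fat(self, spectrum):
        truth = make_phantom(
            grid=(32, 32), num_shots=2, fat_fraction_layout="none", seed=13
        )
        traj = default_trajectory((32, 32), num_shots=2)
        s = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        wf, _ = solve_water_fat(
            s, truth.field_context(), truth.true_phases[0.0], traj, spectrum,
            cg_tol=1e-10, cg_maxiter=300,
        )
        assert np.abs(wf.fat).max() < 1e-6 * np.abs(wf.water).max()

    def test_residual_history_reported(self, small_system):
        b = small_system
        rng = np.random.default_rng(23)
        data = rng.standard_normal((3, 2, 2, 8, 8)) + 1j * rng.standard_normal(
            (3, 2, 2, 8, 8)
        )
        _, res = solve_water_fat(
            ChemShiftEncodedKSpace(data, b["traj"]),
            b["ctx"], b["phases"], b["traj"], b["spectrum"],
        )
        assert len(res.residuals) >= 1
        assert all(r >= 0 for r in res.residuals)


class TestWaterFatMuse:
    def test_reduces_to_sense_for_full_sampling_without_fat(self, spectrum):
        # L=1, lambda=0, fat-free object: per-shot solution equals the
        # SENSE (least-squares coil-combined) image
        rng = np.random.default_rng(31)
        grid = (16, 16)
        traj = EPITrajectory(grid, 1, (0.2e-3,), 0.8e-3)
        csm = np.stack(
            [np.exp(-((np.arange(16)[:, None] - c) ** 2 + (np.arange(16)[None] - 8) ** 2) / 60.0)
             for c in (4, 12)]
        ).astype(complex)
        ctx = FieldContext(b0_map=np.zeros(grid), csm=csm)
        water = rng.standard_normal(grid) + 1j * rng.standard_normal(grid)
        sys = EncodingSystem(
            ctx, ShotPhaseMaps.zeros(1, 1, grid), traj, spectrum,
            use_b0=False, use_shot_phases=False,
        )
        data = sys.forward(WaterFatImage(water, np.zeros(grid)))
        wf = water_fat_muse(
            ChemShiftEncodedKSpace(data, traj), ctx, traj, spectrum,
            lambda_tv=0.0, cg_tol=1e-12, cg_maxiter=500,
        )
        assert nrmse(wf.water[0, 0], water) < 1e-6

    def test_matches_dense_per_shot_oracle(self, spectrum):
        # 4 coils on the 2-shot 8x8 system make every per-(n, l) problem
        # well-posed, so the CG solution must equal the dense pseudo-inverse
        rng = np.random.default_rng(33)
        grid = (8, 8)
        traj = EPITrajectory(grid, 2, (0.2e-3, 1.0e-3, 1.8e-3), 0.8e-3)
        csm = rng.standard_normal((4, 8, 8)) + 1j * rng.standard_normal((4, 8, 8))
        ctx = FieldContext(b0_map=np.zeros(grid), csm=csm)
        sys = EncodingSystem(
            ctx, ShotPhaseMaps.zeros(3, 2, grid), traj, spectrum,
            use_b0=False, use_shot_phases=False,
        )
        x = rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8))
        data = np.zeros((3, 2, 4, 8, 8), complex)
        for n in range(3):
            for l in range(2):
                data[n, l] = sys.encode_nl(x[0], x[1], n, l)
        wf = water_fat_muse(
            ChemShiftEncodedKSpace(data, traj), ctx, traj,
            spectrum, lambda_tv=0.0, cg_tol=1e-13, cg_maxiter=2000,
        )
        for n in range(3):
            for l in range(2):
                A = dense_muse_matrix(traj, spectrum, csm, n, l)
                want = (np.linalg.pinv(A) @ data[n, l].ravel()).reshape(2, 8, 8)
                got = np.stack([wf.water[n, l], wf.fat[n, l]])
                assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-6

    def test_underdetermined_solution_is_data_consistent(self, small_system):
        # with J=L=2 each per-shot system is rank deficient; the minimum-norm
        # CG solution must still predict the data exactly (the well-defined
        # part of the pseudo-inverse comparison)
        b = small_system
        rng = np.random.default_rng(34)
        sys = EncodingSystem(
            b["ctx"], ShotPhaseMaps.zeros(3, 2, (8, 8)), b["traj"], b["spectrum"],
            use_b0=False, use_shot_phases=False,
        )
        x = rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8))
        data = np.zeros((3, 2, 2, 8, 8), complex)
        for n in range(3):
            for l in range(2):
                data[n, l] = sys.encode_nl(x[0], x[1], n, l)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            wf = water_fat_muse(
                ChemShiftEncodedKSpace(data, b["traj"]), b["ctx"], b["traj"],
                b["spectrum"], lambda_tv=0.0, cg_tol=1e-12, cg_maxiter=500,
            )
        for n in range(3):
            for l in range(2):
                pred = sys.encode_nl(wf.water[n, l], wf.fat[n, l], n, l)
                err = np.linalg.norm(pred - data[n, l]) / np.linalg.norm(data[n, l])
                assert err < 1e-6

    def test_tv_solution_approaches_unregularized_limit(self, small_system):
        b = small_system
        rng = np.random.default_rng(35)
        # well-posed single-shot system so the limit is unique
        grid = (8, 8)
        traj = EPITrajectory(grid, 1, (0.2e-3, 1.0e-3, 1.8e-3), 0.8e-3)
        ctx = b["ctx"]
        sys = EncodingSystem(
            ctx, ShotPhaseMaps.zeros(3, 1, grid), traj, b["spectrum"],
            use_b0=False, use_shot_phases=False,
        )
        x = rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8))
        data = np.zeros((3, 1, 2, 8, 8), complex)
        for n in range(3):
            data[n, 0] = sys.encode_nl(x[0], x[1], n, 0)
        ks = ChemShiftEncodedKSpace(data, traj)
        ref = water_fat_muse(ks, ctx, traj, b["spectrum"], lambda_tv=0.0,
                             cg_tol=1e-12, cg_maxiter=500)
        errs = []
        for lam in (1e-2, 1e-4, 1e-6):
            wf = water_fat_muse(ks, ctx, traj, b["spectrum"], lambda_tv=lam,
                                cg_tol=1e-12, cg_maxiter=500, irls_iters=5)
            errs.append(
                np.linalg.norm(wf.water - ref.water) / np.linalg.norm(ref.water)
            )
        assert errs[2] < errs[0]
        assert errs[2] < 1e-3

    def test_underdetermined_system_warns(self, spectrum):
        truth = make_phantom(grid=(32, 32), num_shots=4, num_coils=2, seed=15)
        traj = default_trajectory((32, 32), num_shots=4)
        s = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)
        with pytest.warns(RuntimeWarning):
            water_fat_muse(
                s, truth.field_context(), traj, spectrum, lambda_tv=0.0,
                cg_maxiter=2,
            )

    def test_shared_magnitude_better_conditioned_than_per_shot(self, spectrum):
        # estimating one shared water/fat magnitude across shots beats
        # averaging per-shot estimates on a noisy 6-shot acquisition
        truth = make_phantom(grid=(48, 48), num_shots=6, seed=16, snr=30.0)
        traj = default_trajectory((48, 48), num_shots=6)
        ctx = truth.field_context()
        s = simulate_acquisition(truth, traj, spectrum, bvalue=600.0)
        x = attenuated_truth(truth, 600.0)
        wf_joint, _ = solve_water_fat(
            s, ctx, truth.true_phases[600.0], traj, spectrum
        )
        per_shot = water_fat_muse(s, ctx, traj, spectrum)
        avg_water = np.abs(per_shot.water).mean(axis=(0, 1))
        err_joint = nrmse(np.abs(wf_joint.water), np.abs(x.water))
        err_avg = nrmse(avg_water, np.abs(x.water))
        assert err_joint < err_avg


class TestPhaseExtraction:
    def test_merged_phase_examples(self):
        rng = np.random.default_rng(41)
        w = rng.standard_normal((2, 2, 8, 8)) + 1j * rng.standard_normal((2, 2, 8, 8))
        f = rng.standard_normal((2, 2, 8, 8)) + 1j * rng.standard_normal((2, 2, 8, 8))
        got = merged_phase(ShotWaterFat(water=w, fat=f))
        np.testing.assert_allclose(got.phases, np.angle(w + f))

    def test_merged_phase_trivial_cases(self):
        mag = np.abs(np.random.default_rng(43).standard_normal((1, 1, 4, 4))) + 0.1
        real_pos = merged_phase(ShotWaterFat(water=mag + 0j, fat=np.zeros_like(mag)))
        assert not real_pos.phases.any()
        imag = merged_phase(ShotWaterFat(water=1j * mag, fat=np.zeros_like(mag)))
        np.testing.assert_allclose(imag.phases, np.pi / 2)

    def test_merged_phase_zero_magnitude_voxels_get_zero_phase(self):
        w = np.full((1, 1, 4, 4), 1.0 + 1.0j)
        w[0, 0, 0, 0] = 1e-12
        got = merged_phase(ShotWaterFat(water=w, fat=np.zeros_like(w)))
        assert got.phases[0, 0, 0, 0] == 0.0

    def test_diffusion_phase_subtraction_wraps(self):
        a = ShotPhaseMaps(np.full((1, 1, 2, 2), 3.0))
        b = ShotPhaseMaps(np.full((1, 1, 2, 2), -3.0))
        got = init_diffusion_phase(a, b)
        np.testing.assert_allclose(got.phases, 6.0 - 2 * np.pi, atol=1e-12)

    def test_diffusion_phase_identical_inputs_zero(self):
        a = ShotPhaseMaps(np.random.default_rng(47).standard_normal((2, 2, 4, 4)))
        got = init_diffusion_phase(a, a)
        np.testing.assert_allclose(got.phases, 0.0, atol=1e-12)

    def test_diffusion_phase_zero_reference_wraps_input(self):
        a = ShotPhaseMaps(np.full((1, 1, 2, 2), 4.0))
        z = ShotPhaseMaps.zeros(1, 1, (2, 2))
        got = init_diffusion_phase(a, z)
        np.testing.assert_allclose(got.phases, 4.0 - 2 * np.pi, atol=1e-12)

    def test_diffusion_phase_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            init_diffusion_phase(
                ShotPhaseMaps.zeros(1, 1, (4, 4)), ShotPhaseMaps.zeros(1, 2, (4, 4))
            )
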