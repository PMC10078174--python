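import numpy as np
import pytest
from hypothesis import settings

from msnd import (
    FieldContext,
    ReconConfig,
    ShotPhaseMaps,
    apply_masks_to_csm,
    default_six_peak_model,
    default_trajectory,
    make_masks,
    make_phantom,
    msnd_reconstruct,
    simulate_acquisition,
    solve_water_fat,
)
from msnd.encoding import EPITrajectory

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spectrum():
    return default_six_peak_model(3.0)


@pytest.fixture(scope="session")
def small_system(spectrum):
    """8x8 grid, 2 coils, 2 shots, 3 encodings with smooth random maps."""
    rng = np.random.default_rng(7)
    grid = (8, 8)
    traj = EPITrajectory(
        matrix=grid, num_shots=2, delta_te=(0.2e-3, 1.0e-3, 1.8e-3), echo_spacing=0.8e-3
    )
    csm = rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8))
    b0 = 60.0 * rng.standard_normal(grid)
    phases = ShotPhaseMaps(0.8 * rng.standard_normal((3, 2) + grid))
    ctx = FieldContext(b0_map=b0, csm=csm)
    return {"traj": traj, "ctx": ctx, "phases": phases, "spectrum": spectrum, "rng": rng}


@pytest.fixture(scope="session")
def phantom_bundle(spectrum):
    """Default 64x64 / 4-coil / 4-shot phantom with b=0 and b=600 data."""
    truth = make_phantom(seed=1)
    traj = default_trajectory(truth.grid, num_shots=4)
    ctx = truth.field_context()
    s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0)
    s600 = simulate_acquisition(truth, traj, spectrum, bvalue=600.0)
    zero = ShotPhaseMaps.zeros(3, 4, truth.grid)
    wf0, _ = solve_water_fat(s0, ctx, zero, traj, spectrum)
    wm, fm = make_masks(wf0)
    ctxm = apply_masks_to_csm(ctx, wm, fm)
    return {
        "truth": truth,
        "traj": traj,
        "ctx": ctxm,
        "s0": s0,
        "s600": s600,
        "wf0": wf0,
    }


@pytest.fixture(scope="session")
def msnd_result(phantom_bundle, spectrum):
    """Self-navigated reconstruction of the noisy b=600 data (shared)."""
    b = phantom_bundle
    wf, phases, diag = msnd_reconstruct(
        b["s600"], b["ctx"], b["traj"], spectrum, ReconConfig(), init="zero"
    )
    return {"wf": wf, "phases": phases, "diag": diag}


@pytest.fixture(scope="session")
def zero_phase_result(phantom_bundle, spectrum):
    """Same data reconstructed with shot-phase estimation disabled."""
    b = phantom_bundle
    zero = ShotPhaseMaps.zeros(3, 4, b["truth"].grid)
    wf, _ = solve_water_fat(b["s600"], b["ctx"], zero, b["traj"], spectrum)
    return {"wf": wf}
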