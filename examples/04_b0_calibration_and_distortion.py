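"""B0/water/fat calibration from b=0 data and geometric distortion handling.

The non-diffusion data carry no motion phases, so their inter-encoding phase
structure determines the off-resonance map. The estimated field then serves
two geometric purposes: distorting prescan coil maps into the EPI geometry
(inverse conjugate-phase) and undistorting the final images (CPR).
"""
import numpy as np

from msnd import (
    FieldContext, calibrate_csm_b0, cpr_correct, default_six_peak_model,
    default_trajectory, estimate_b0_water_fat, make_phantom, nrmse,
    simulate_acquisition,
)

spectrum = default_six_peak_model(3.0)
truth = make_phantom(seed=2, b0_range_hz=150.0)
traj = default_trajectory(truth.grid, num_shots=4)
s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0, noise_sigma=0.0)

ctx = FieldContext(b0_map=np.zeros(truth.grid), csm=truth.csm)
psi, wf = estimate_b0_water_fat(s0, ctx, traj, spectrum)
support = truth.support()
rmse = np.sqrt(np.mean((psi - truth.b0_map)[support] ** 2))
print(f"B0 estimate: RMSE {rmse:.2f} Hz on support (true range +-150 Hz)")
print(f"b=0 water NRMSE {100*nrmse(np.abs(wf.water), np.abs(truth.water)):.2f}%, "
      f"fat NRMSE {100*nrmse(np.abs(wf.fat), np.abs(truth.fat)):.2f}%")

# distort prescan coil maps to EPI geometry, then undo with CPR
moderate = make_phantom(seed=3, b0_range_hz=50.0)
d = calibrate_csm_b0(moderate.csm, moderate.b0_map, traj)
back = np.stack([cpr_correct(d[j], moderate.b0_map, traj) for j in range(4)])
sup = moderate.support()
err = np.linalg.norm((back - moderate.csm)[:, sup]) / np.linalg.norm(moderate.csm[:, sup])
print(f"CSM distortion -> CPR round trip: {100*err:.2f}% NRMSE on the object")
# The field map is accurate to a few Hz and the conjugate-phase pair inverts
# itself to within ~2% for a shimmed-extremity-scale field.
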