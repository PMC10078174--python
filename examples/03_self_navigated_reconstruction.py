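"""Self-navigated reconstruction of diffusion-weighted data.

The DW shots carry unknown smooth motion-induced phase maps. Ignoring them
(zero-valued phase maps) scrambles the phase relations between the chemical
shift encodings and leaves fat in the water image; the Gauss-Newton
self-navigation estimates the phases from the imaging data itself and
restores the separation.
"""
import numpy as np

from msnd import (
    ReconConfig, ShotPhaseMaps, apply_masks_to_csm, default_six_peak_model,
    default_trajectory, make_masks, make_phantom, msnd_reconstruct, nrmse,
    simulate_acquisition, solve_water_fat,
)
from msnd.evaluation import fat_leakage_ratio
from msnd.simulator import attenuated_truth

truth = make_phantom(seed=1)  # image SNR 30, phase amplitude pi/2
traj = default_trajectory(truth.grid, num_shots=4)
spectrum = default_six_peak_model(3.0)
ctx = truth.field_context()
s0 = simulate_acquisition(truth, traj, spectrum, bvalue=0.0)
s600 = simulate_acquisition(truth, traj, spectrum, bvalue=600.0)

# b=0 preparation: water/fat masks multiplied into the coil operator
zero = ShotPhaseMaps.zeros(3, 4, truth.grid)
wf0, _ = solve_water_fat(s0, ctx, zero, traj, spectrum)
wm, fm = make_masks(wf0)
ctxm = apply_masks_to_csm(ctx, wm, fm)

wf, phases, diag = msnd_reconstruct(s600, ctxm, traj, spectrum, ReconConfig(), init="zero")
wfz, _ = solve_water_fat(s600, ctxm, zero, traj, spectrum)

x = attenuated_truth(truth, 600.0)
print("normalized residual per GN iteration:",
      " ".join(f"{r:.3f}" for r in diag["residuals"]))
for name, w in [("self-navigated", wf.water), ("zero-phase", wfz.water)]:
    print(f"{name:15s} water NRMSE {100*nrmse(np.abs(w), np.abs(x.water)):5.1f}%  "
          f"fat leakage {100*fat_leakage_ratio(w, truth, 600.0):5.1f}% of water max")
# The residual drops to the noise floor within the 8-iteration budget; the
# fixed-zero-phase solve leaks an order of magnitude more fat into water.
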