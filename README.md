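# msnd — self-navigated water/fat decomposition for DW multishot EPI

Diffusion-weighted multishot EPI outside the brain faces two coupled phase
problems. Physiological motion interacting with the diffusion gradients
imprints a different smooth phase map φ<sub>n,l</sub>(r) on every shot, and
fat — whose chemical shift displaces it along the phase-encode direction and
which is barely attenuated by diffusion — overlaps the water anatomy whenever
spectral fat suppression fails in inhomogeneous B<sub>0</sub>. Chemical shift
encoding (repeating the acquisition at N echo-time shifts ΔTE<sub>n</sub>)
makes water/fat separation possible, but classic approaches need an extra 2D
navigator per shot to measure the motion phases, costing 30–35% of scan
efficiency and themselves suffering from the shifted fat.

`msnd` implements a model-based, **self-navigated** reconstruction: water and
fat images and all shot phase maps are estimated jointly, directly from the
multi-coil k-space data. The signal model per encoding n, shot l, coil j is

```
s_{n,l,j}(k_t) = ∫ c_j(r) [ ρ_w(r) + Σ_m α_m e^{-i2π ψ_{f,m}(ΔTE_n + t)} ρ_f(r) ]
                 · e^{-i2π ψ_B(r) ΔTE_n} · e^{-i φ_{n,l}(r)} · e^{-i k_t·r} dr
```

with a multi-peak fat spectrum (α<sub>m</sub>, ψ<sub>f,m</sub>), off-resonance
map ψ<sub>B</sub> and coil sensitivities c<sub>j</sub>. Because the chemical
shift is spatially invariant, the fat off-resonance becomes a per-EPI-line
weight on the fat channel's k-space — this is what encodes (and corrects) the
fat displacement. For fixed phases the water/fat problem
min<sub>X</sub>‖ÂX − S‖² is solved by conjugate gradients; the phase maps are
updated by a Gauss-Newton linearization e^{-iφ}(1 − iΔφ) with real-valued Δφ
unknowns, k-space triangular-window smoothing of each phase map, and
re-solving for water/fat — repeated until the normalized residual falls below
10⁻⁴ or 8 iterations. A per-shot SENSE-type water/fat solve ("water-fat
MUSE", TV-regularized) provides optional phase initialization, and the b = 0
data (which carry no motion phase) supply the B<sub>0</sub> map, water/fat
masks and calibrated coil maps. Conjugate-phase reconstruction (CPR) removes
the B<sub>0</sub> geometric distortion as post-processing, and the same
machinery distorts prescan coil maps *into* the EPI geometry.

The package is a library plus a built-in phantom simulator (no in-vivo data
are distributed); a thin CLI (`msnd simulate|reconstruct|evaluate`) covers
the file-based workflow.

## Worked example

`examples/03_self_navigated_reconstruction.py` simulates the default 64×64,
4-shot, 4-coil, three-point-encoded (ΔTE = 0.2/1.0/1.8 ms) acquisition at
b = 600 s/mm² with unknown smooth shot phases (amplitude π/2) at image SNR
30, then reconstructs with and without self-navigation:

```
normalized residual per GN iteration: 0.530 0.173 0.119 0.114 0.112 0.112 0.111 0.111 0.111
self-navigated  water NRMSE   3.1%  fat leakage   1.0% of water max
zero-phase      water NRMSE  28.1%  fat leakage   9.5% of water max
```

The Gauss-Newton residual drops to the noise floor within the 8-iteration
budget; with phase estimation disabled the shot-to-shot phase errors destroy
the inter-encoding phase relations and roughly ten times more fat leaks into
the water image. The other examples cover the simulator
(`01_simulate_acquisition.py`), the linear separation in isolation (`02`,
recovering noiseless data to ~10⁻⁷ NRMSE), B<sub>0</sub> calibration and
distortion correction (`04`: 0.2 Hz field-map RMSE on a ±150 Hz field, 1.8%
CPR round-trip error) and ADC/CoV evaluation (`05`: median fitted ADC
1.486×10⁻³ mm²/s for a 1.5×10⁻³ ground truth).

## Layout

- `src/msnd/fat_model.py` — multi-peak fat spectrum and modulation weights
- `src/msnd/encoding.py` — trajectory, containers, forward model and adjoint
- `src/msnd/simulator.py` — phantom and raw-data simulator (model-consistent
  and realistic modes)
- `src/msnd/separation.py` — CG water/fat solve, water-fat MUSE, phase
  extraction and b=0 subtraction
- `src/msnd/core.py` — the Gauss-Newton self-navigation loop
- `src/msnd/calibration.py` — B0/water/fat estimation, masks, CSM
  calibration, CPR
- `src/msnd/evaluation.py` — CoV, ADC fitting, recovery metrics, comparators
- `docs/methods.md` — model, assumptions, parameter choices and limitations
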