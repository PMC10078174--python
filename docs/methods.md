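# Methods

## Signal model and operators

The acquisition model treats each k-space sample of encoding n, shot l and
coil j as the Fourier integral of the coil-weighted water/fat object carrying
three phase factors: the multi-peak fat modulation
Σ_m α_m e^{-i2π ψ_{f,m}(ΔTE_n + t)}, the off-resonance phase
e^{-i2π ψ_B ΔTE_n}, and the motion-induced shot phase e^{-i φ_{n,l}}. Two
deliberate approximations define the *reconstruction* model:

- **B0 during the readout is ignored** — only the encoding-shift phase
  e^{-i2π ψ_B ΔTE_n} is modeled. The per-line dephasing e^{-i2π ψ_B t} that
  causes geometric distortion is excluded from inversion and instead handled
  by conjugate-phase correction as post-processing. The simulator's
  "realistic" mode applies it, so the mismatch is testable.
- **Fat modulation is a per-line weight.** Since the chemical shift is
  spatially invariant, the fat phase factor commutes with the Fourier
  integral; each phase-encode line of the fat channel's k-space is scaled by
  the weight at τ = ΔTE_n + t(line). Time is assigned per line
  (center-of-line approximation); intra-line (frequency-encode) timing is
  neglected because the fat displacement along frequency-encode is sub-pixel
  at typical bandwidths.

Conventions: image axes are (phase-encode, frequency-encode); the forward
kernel is e^{-ik·r} realized as a centered orthonormal FFT (DC at
`n // 2`); interleaved shot l acquires lines l, l+L, … in ascending order.
Line times are linear across ky with slope `echo_spacing / L` — interleaved
ms-EPI staggers each shot's readout window by `echo_spacing·l/L` precisely so
the phase evolution is continuous across the combined k-space — making
`echo_spacing / L` the effective dwell that converts off-resonance (Hz) into
phase-encode displacement (pixels × 1/FOV).

Water/fat masks derived from the b = 0 images multiply into the
coil-sensitivity operator of the respective channel, restricting each
species' support (threshold 0.03 of the maximum magnitude, one binary
erosion, three dilations, 3×3 cross element).

## Solvers

All linear systems are solved by conjugate gradients on the normal equations
with the real part of the Euclidean inner product, which handles both
complex unknowns and the mixed complex/real Gauss-Newton system (real/imag
parts of ΔΡ_w, ΔΡ_f plus real ΔΦ packed into one real vector). Defaults:
tolerance 10⁻³ with 20 iterations for the main water/fat and Gauss-Newton
systems; 10⁻² with 10 iterations for the MUSE initializer. A non-positive
curvature direction flags a breakdown and returns the best iterate with its
residual history.

The Gauss-Newton loop linearizes e^{-i(φ+Δφ)} ≈ e^{-iφ}(1 − iΔφ); the
Jacobian applies the frozen system Â to the channel inputs
(ΔΡ_w − iΡ_w ΔΦ_{n,l}, ΔΡ_f − iΡ_f ΔΦ_{n,l}) — the −i sign is used uniformly
for both species, as the Taylor expansion forces. Each iteration updates the
phases, smooths them, re-solves the linear water/fat problem (warm-started),
and records the normalized data residual ‖S − ÂX‖/‖S‖. The loop stops below
10⁻⁴, after 8 iterations, or when an iteration fails to decrease the
residual (the update is rejected and the best iterate kept, so the accepted
residual history is non-increasing). An update-norm convergence metric is
available through `ReconConfig.convergence_metric`. One constant added to
every phase map against an opposite global rotation of the images is an
exact gauge freedom; recoveries are therefore compared after global
complex-scale alignment, and phase errors after removing a per-map constant.

**Phase smoothing.** Smoothness of each phase map is enforced by a centered
separable 2D triangular k-space window (full width `window_fraction` × matrix,
default 5/7; 1/2 suits finer-resolution protocols) applied to the phasor,
then re-extracting the angle. Inside the Gauss-Newton loop the phasor is
weighted by the current |Ρ_w| + |Ρ_f| magnitude before filtering
(`ReconConfig.phase_smoothing_weighting`, default `"magnitude"`): filtering
the *unit* phasor lets the meaningless zero-phase background bleed several
pixels across the object edge — exactly where subcutaneous fat sits — and
measurably stalls convergence; weighting by magnitude (i.e., filtering the
complex image, as MUSE-style methods do) removes that edge bias. The public
`smooth_phase` retains the unit-phasor form as its default.

## Initialization (water-fat MUSE)

Each (encoding, shot) dataset is an L-fold undersampled SENSE-type water/fat
problem with the B0 and motion-phase operators dropped. It is solved per
(n, l) with isotropic ε-smoothed total variation (ε = 10⁻⁶ × data scale,
weight λ = 0.01) by iteratively reweighted least squares — three reweightings,
each inner system by CG at the initializer tolerances — so CG remains the
only linear solver. The merged phase angle(Ρ̃_w + Ρ̃_f) (unit weights; a
weight option exists) is extracted per (n, l), the b = 0 merged phase is
subtracted wrap-safely as angle(e^{i(Φ_b − Φ_b0)}), and the result, smoothed,
initializes the Gauss-Newton loop. Voxels below 10⁻⁸ of the per-map maximum
get phase zero rather than the angle of numerical noise. With few coils per
shot the per-shot systems are underdetermined (a warning is raised); the
regularized solution is still a useful phase prior, which is exactly why the
joint model — one shared magnitude, per-shot phases — is better conditioned
than per-shot separation, a property the test suite checks directly.

## b = 0 calibration

At b = 0 the motion phases vanish, leaving ψ_B as the only nonlinear
unknown. The estimator has three stages:

1. **Per-voxel frequency search** (VARPRO-style) on shot- and coil-combined
   per-encoding images over ±500 Hz in 5 Hz steps: for each candidate the
   demodulated signals are projected onto span{1, β_n} (β_n the fat weight at
   ΔTE_n) and the residual minimized. The step must be fine enough that
   quantization of the true frequency costs less residual than the
   multi-peak asymmetry separating the water/fat-swap branch (~434 Hz away at
   3 T). Because this image-domain model ignores the fat displacement, voxels
   contaminated by displaced fat fit poorly or wrongly; the map is therefore
   median-filtered (5×5) and smoothed by normalized convolution weighted by
   magnitude × fit-confidence.
2. **Gauss-Newton refinement** on the full k-space model (which does encode
   the displacement), with per-(n) channel inputs ΔΡ − i2πΔTE_n Ρ Δψ. The
   frequency update is masked at the 3% magnitude threshold (updates in
   signal-free voxels are noise) and, for the first 6 of 12 iterations,
   smoothed by the same magnitude-weighted triangular normalized
   convolution; the remaining iterations apply unsmoothed masked updates.
   Rationale: smoothing the update (not the accumulated map) converges to
   the true field on every mode inside the window, but modes near the window
   edge drain at only a few percent per iteration, so a final unsmoothed
   refinement is needed for sub-Hz accuracy; by then the per-voxel problem
   (3 encodings, 5 real unknowns) is well posed. Two consecutive residual
   increases return the best iterate with a warning. Initializing at the
   swap frequency demonstrably converges to the swapped minimum — the test
   suite documents this hazard rather than hiding it.
3. **Coil-map calibration.** Prescan maps are adapted to the EPI geometry by
   the inverse conjugate-phase distortion (per-line modulation
   e^{-i2π ψ_B t(line)}), the exact forward counterpart of the CPR
   correction. Alternatively, a smoothed-ratio autocalibration estimates
   maps from the b = 0 data itself: per coil, a water/fat solve with the
   known B0 (removing the fat displacement) yields a merged composite, which
   is Gaussian-smoothed (σ = 3 px) and divided by the root-sum-of-squares
   composite. This keeps the two-step structure (field map first,
   position-corrected merged-species maps second) with the simplest
   defensible estimator; eigenvalue-decomposition calibration is out of
   scope. Data-driven maps inherit the common voxelwise image phase and a
   global scale; `csm_alignment_error` removes both before comparison.

**CPR** demodulates each phase-encode line of an image's k-space by
e^{+i2π ψ_B(r) t(line)} voxelwise, as an explicit O(Npe²·Nfe) sum —
acceptable at matrix sizes up to ~160 and exact for constant fields. The
distort/correct pair is a first-order inverse: round-trip error grows with
the field range (≈1.8% at ±50 Hz, ≈2.4% at ±100 Hz on the 64×64 phantom) and
is evaluated on the object support because the FOV-boundary rows carry a
periodic-wrap artifact of the discrete torus with no physical meaning.

## Simulator

The phantom emulates an extremity/head-neck slice: a water ellipse with
smooth texture and smooth spatial phase, a subcutaneous fat ring, a fat-only
marrow disk (providing the fat-only region in which water-channel leakage is
measured), a low-order-polynomial B0 field bounded by ±`b0_range_hz`
(default 100 Hz), and Gaussian-lobe coil maps with smooth phase. Defaults
mirror a desk-scale version of the study conditions: 64×64 matrix, 4 coils,
L = 4 shots (2/6 available), N = 3 encodings at ΔTE = 0.2/1.0/1.8 ms, echo
spacing 0.8 ms, b = 0/300/600 s/mm², muscle-like ADC 1.5×10⁻³ mm²/s applied
to water only (fat is left unattenuated, consistent with its negligible
diffusion attenuation).

Shot phases at b > 0 are a random constant (70% of the amplitude budget,
default π/2 total) plus a periodic low-spatial-frequency harmonic field
(modes ≤ 2 cycles/FOV, amplitudes ∝ |k|⁻²): bulk motion dominates real
diffusion phase errors, and periodic harmonics keep the maps inside the
invariance class of the triangular smoothing window the estimator assumes
(a non-periodic polynomial has Gibbs content at the FOV edge that no
windowed estimator could represent). A non-periodic linear-ramp option
exists. b = 0 phases are identically zero (no diffusion gradients). No
quantitative in-vivo distribution for these phases exists; amplitude and
smoothness are configuration, not asserted physiology.

**Noise.** "SNR" is quoted the way a DWI acquisition's SNR is: the voxel SNR
of the matched-filter coil-combined water image at the largest b-value. The
i.i.d. complex k-space noise std per coil sample is derived from it through
the combination gain √(N·mean Σ_j|c_j|²); noise is added only at sampled
points and is independent across coils. Default SNR 30.

**What the simulator does not model:** bulk motion between shots,
eddy-current field perturbations, T2/T2* decay across the echo train (and
hence the fat-amplitude "self-calibration" at a reference TE, exposed as an
identity-default hook), EPI readout-polarity/Nyquist-ghost effects (assumed
corrected upstream), coil noise covariance, and non-Cartesian or
partial-Fourier sampling. Passing tests therefore demonstrate correctness of
the stated model and robustness to noise, smooth off-resonance and smooth
shot phases — not to those unmodeled effects.

## Fat spectrum

Six-peak triglyceride table at ppm offsets −3.80/−3.40/−2.60/−1.94/−0.39/
+0.60 relative to water with relative amplitudes
0.087/0.693/0.128/0.004/0.039/0.048 (renormalized to sum 1); gyromagnetic
ratio fixed at 42.577 MHz/T. The dominant methylene peak at −3.4 ppm gives
−434 Hz at 3 T and the ~2.3 ms water–methylene in-phase period; note that the
*full* six-peak weight at 2.3 ms has magnitude ≈0.82 because the secondary
peaks keep dephasing — in-phase statements apply to the methylene line. The
table and field strength are fully user-overridable (YAML/JSON block).

## Evaluation conventions

- NRMSE after aligning one global complex scale (the gauge); water-magnitude
  NRMSE is gauge-free. Phase RMSE on the object support after removing a
  per-map constant.
- **Fat-into-water leakage**: mean |water estimate| over ground-truth
  fat-only voxels, relative to the peak true DW water magnitude. The mean is
  used because a per-voxel maximum over hundreds of voxels measures the
  noise tail (≈3σ) at any finite SNR, not separation quality; the max
  statistic remains available.
- CoV = sample SD / mean (divisor n − 1) of the magnitude within an ROI.
- ADC by joint log-linear least squares over all b-values; voxels with any
  nonpositive magnitude are NaN, never clipped. A two-point mode exists for
  parity checks.
- The "extra-navigator" comparator fixes the phase maps to a low-pass view
  of the true phases (emulating a low-resolution navigator) and runs the
  linear solve — enough to reproduce the failure mode without reimplementing
  an image-based navigated pipeline.

## Problem sizes and budgets

Tests and the acceptance script run at 8×8 (dense oracles), 32–48² (unit
tests) and 64×64 (end-to-end recovery), with 2–6 shots and 1–4 coils —
deliberately desk-scale versions of the 116–168 matrix, 8–16 coil protocols
the method targets. At 64×64/4-shot/4-coil the full self-navigated
reconstruction takes a few seconds per b-value on one CPU core.

## Known limitations

- The Gauss-Newton problem is non-convex; with zero initialization and phase
  amplitudes well beyond π/2, or severe fat-dominated anatomy, convergence to
  swapped or local minima is possible (MUSE initialization mitigates this).
- CPR is first-order in the field variation; strong field gradients leave
  residual blur/displacement.
- The B0 estimator's frequency search assumes the true field lies within
  ±500 Hz and at least 3 encodings are available.
- Each (b-value, direction) is reconstructed independently; no joint
  multi-b-value model, no undersampling beyond the shot structure.
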