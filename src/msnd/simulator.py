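"""Synthetic phantoms and raw chemical-shift-encoded DW ms-EPI data.

The phantom emulates an extremity/head-neck-like slice: a water-dominated
interior, a subcutaneous fat ring, a fat-only "marrow" disk, smooth coil
sensitivities, a smooth low-order-polynomial B0 field, and spatially smooth
random shot-to-shot phase maps for the diffusion-weighted acquisitions
(non-diffusion data carry no motion phase because the diffusion gradients are
off). Two acquisition modes exist:

* ``model_consistent`` — data generated exactly by the reconstruction model
  (B0 enters only through the encoding-shift phase);
* ``realistic`` — additionally applies the per-line B0 dephasing
  ``exp(-i 2 pi psiB t(line))`` during the EPI readout, producing genuine
  geometric distortion that the model does not describe (used to exercise the
  conjugate-phase distortion correction).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .encoding import (
    ChemShiftEncodedKSpace,
    EncodingSystem,
    EPITrajectory,
    FieldContext,
    ShotPhaseMaps,
    WaterFatImage,
)
from .fat_model import FatSpectrum
from .linalg import fft2c

DEFAULT_DELTA_TE = (0.2e-3, 1.0e-3, 1.8e-3)  # s, three-point encoding
DEFAULT_ECHO_SPACING = 0.8e-3  # s
DEFAULT_BVALUES = (0.0, 300.0, 600.0)  # s/mm^2


@dataclass
class PhantomGroundTruth:
    """Ground truth for a simulated acquisition, fully seeded."""

    water: np.ndarray
    fat: np.ndarray
    b0_map: np.ndarray
    csm: np.ndarray
    true_phases: Dict[float, ShotPhaseMaps]
    bvalues: tuple
    adc_map: np.ndarray
    noise_sigma: float
    seed: int

    @property
    def grid(self):
        return self.water.shape

    def field_context(self) -> FieldContext:
        return FieldContext(b0_map=self.b0_map, csm=self.csm)

    def support(self, rel_threshold: float = 0.05) -> np.ndarray:
        mag = np.abs(self.water) + np.abs(self.fat)
        return mag > rel_threshold * mag.max()


def _grid_coords(grid):
    npe, nfe = grid
    y = (np.arange(npe) - npe / 2 + 0.5) / (npe / 2)
    x = (np.arange(nfe) - nfe / 2 + 0.5) / (nfe / 2)
    return np.meshgrid(y, x, indexing="ij")


def _smooth_random_field(grid, max_mode: int, rng, decay: float = 1.0) -> np.ndarray:
    """Real periodic random field from harmonics with |k|_inf <= max_mode.

    Periodicity keeps the field inside the invariance class of the k-space
    triangular smoothing window (no Gibbs overshoot at the FOV edge); the
    harmonic amplitudes fall off as |k|^-decay.
    """
    npe, nfe = grid
    Y, X = np.meshgrid(np.arange(npe) / npe, np.arange(nfe) / nfe, indexing="ij")
    f = np.zeros(grid)
    for ky in range(-max_mode, max_mode + 1):
        for kx in range(0, max_mode + 1):
            if kx == 0 and ky <= 0:
                continue
            amp = rng.normal() / max(1.0, np.hypot(ky, kx)) ** decay
            pha = rng.uniform(0, 2 * np.pi)
            f += amp * np.cos(2 * np.pi * (ky * Y + kx * X) + pha)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def draw_shot_phases(
    grid,
    num_encodings: int,
    num_shots: int,
    smoothness: int = 2,
    amplitude_rad: float = np.pi / 2,
    seed: int = 0,
    constant_fraction: float = 0.7,
    include_ramp: bool = False,
) -> ShotPhaseMaps:
    """Random smooth motion-phase maps, one per (encoding, shot).

    Each map is a random constant (bulk phase offset, ``constant_fraction`` of
    the amplitude budget) plus a periodic low-spatial-frequency field with
    harmonics up to ``smoothness`` cycles per FOV. ``include_ramp`` adds a
    non-periodic linear ramp (at the cost of leaving the smoothing window's
    invariance class near the FOV edge). ``amplitude_rad`` bounds the total
    peak phase.
    """
    if amplitude_rad < 0:
        raise ValueError("amplitude must be nonnegative")
    rng = np.random.default_rng(seed)
    Y, X = _grid_coords(grid)
    phases = np.zeros((num_encodings, num_shots) + tuple(grid))
    spatial_amp = (1.0 - constant_fraction) * amplitude_rad
    for n in range(num_encodings):
        for l in range(num_shots):
            const = rng.uniform(-1, 1) * constant_fraction * amplitude_rad
            spatial = spatial_amp * _smooth_random_field(grid, smoothness, rng, decay=2.0)
            if include_ramp:
                spatial = 0.5 * spatial + 0.5 * spatial_amp * (
                    rng.uniform(-1, 1) * Y + rng.uniform(-1, 1) * X
                )
            phases[n, l] = const + spatial
    return ShotPhaseMaps(phases)


def make_phantom(
    grid=(64, 64),
    num_coils: int = 4,
    fat_fraction_layout: str = "ring_and_marrow",
    b0_range_hz: float = 100.0,
    seed: int = 0,
    num_encodings: int = 3,
    num_shots: int = 4,
    bvalues=DEFAULT_BVALUES,
    phase_amplitude_rad: float = np.pi / 2,
    adc: float = 1.5e-3,
    snr: float = 30.0,
) -> PhantomGroundTruth:
    """Build a deterministic leg/head-neck-like numerical phantom.

    ``fat_fraction_layout`` is ``"ring_and_marrow"`` (subcutaneous ring plus a
    fat-only marrow disk, with a thin water/fat overlap band), ``"ring"`` or
    ``"none"``. ``snr`` is the voxel SNR of the coil-combined water image at
    the largest b-value (the usual way a DWI acquisition's SNR is quoted);
    the k-space noise standard deviation is derived from it through the
    matched-filter combination gain. ``b0_range_hz`` bounds the smooth
    polynomial B0 field. Identical seeds give identical phantoms.
    """
    grid = tuple(grid)
    if grid[0] < 16 or grid[1] < 16:
        raise ValueError("grid must be at least 16 x 16")
    if num_coils < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(seed)
    Y, X = _grid_coords(grid)
    r = np.sqrt((X / 0.80) ** 2 + (Y / 0.88) ** 2)

    # water: interior of the body ellipse with smooth texture
    interior = r < 0.66
    texture = 1.0 + 0.25 * np.exp(-((X + 0.2) ** 2 + (Y - 0.1) ** 2) / 0.18)
    water = interior * texture
    water_phase = 0.3 * _smooth_random_field(grid, 1, rng)
    water = water * np.exp(1j * water_phase)

    # fat: subcutaneous ring and marrow disk
    fat = np.zeros(grid, complex)
    marrow = np.zeros(grid, bool)
    if fat_fraction_layout in ("ring_and_marrow", "ring"):
        ring = (r >= 0.62) & (r < 0.82)
        fat = fat + 0.9 * ring
    if fat_fraction_layout == "ring_and_marrow":
        marrow = ((X - 0.22) ** 2 + (Y + 0.18) ** 2) < 0.12**2
        fat = fat + 1.0 * marrow
        water = water * ~marrow  # marrow is fat-only
    elif fat_fraction_layout not in ("ring", "none"):
        raise ValueError(f"unknown fat_fraction_layout {fat_fraction_layout!r}")
    fat = fat * np.exp(1j * 0.3 * _smooth_random_field(grid, 1, rng))

    # smooth polynomial B0 bounded by +-b0_range_hz
    coeffs = rng.uniform(-1, 1, size=6)
    poly = (
        coeffs[0]
        + coeffs[1] * X
        + coeffs[2] * Y
        + coeffs[3] * X * Y
        + coeffs[4] * X**2
        + coeffs[5] * Y**2
    )
    peak = np.abs(poly).max()
    b0 = b0_range_hz * poly / peak if (peak > 0 and b0_range_hz > 0) else np.zeros(grid)

    # smooth coil sensitivities: Gaussian lobes around the object
    csm = np.zeros((num_coils,) + grid, complex)
    for j in range(num_coils):
        ang = 2 * np.pi * j / num_coils
        cy, cx = 1.35 * np.sin(ang), 1.35 * np.cos(ang)
        mag = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 0.75**2))
        pha = 0.5 * (X * np.cos(ang + 0.7) + Y * np.sin(ang + 0.7))
        csm[j] = mag * np.exp(1j * pha)
    rss = np.sqrt(np.sum(np.abs(csm) ** 2, axis=0))
    csm /= rss.max()
    rss_sq = np.sum(np.abs(csm) ** 2, axis=0)

    adc_map = adc * (np.abs(water) > 0)
    # noise level defined by the voxel SNR of the matched-filter coil-combined
    # water image at the largest b-value (the DWI-image SNR convention):
    # combined image noise std ~= sigma_k / sqrt(N * sum_j |c_j|^2)
    wsup = np.abs(water) > 0
    bmax = max(bvalues)
    mean_dw_water = float(np.abs(water * np.exp(-bmax * adc_map))[wsup].mean())
    gain = np.sqrt(num_encodings * float(rss_sq[wsup].mean()))
    noise_sigma = mean_dw_water * gain / snr if snr > 0 else 0.0

    true_phases: Dict[float, ShotPhaseMaps] = {}
    for i, b in enumerate(bvalues):
        if b == 0:
            true_phases[b] = ShotPhaseMaps.zeros(num_encodings, num_shots, grid)
        else:
            true_phases[b] = draw_shot_phases(
                grid,
                num_encodings,
                num_shots,
                amplitude_rad=phase_amplitude_rad,
                seed=int(rng.integers(2**31 - 1)),
            )
    return PhantomGroundTruth(
        water=water,
        fat=fat,
        b0_map=b0,
        csm=csm,
        true_phases=true_phases,
        bvalues=tuple(bvalues),
        adc_map=adc_map,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def default_trajectory(
    grid=(64, 64),
    num_shots: int = 4,
    delta_te=DEFAULT_DELTA_TE,
    echo_spacing: float = DEFAULT_ECHO_SPACING,
) -> EPITrajectory:
    """Desk-scale three-point-encoded interleaved EPI trajectory."""
    return EPITrajectory(
        matrix=grid, num_shots=num_shots, delta_te=delta_te, echo_spacing=echo_spacing
    )


def attenuated_truth(truth: PhantomGroundTruth, bvalue: float) -> WaterFatImage:
    """Diffusion-attenuated ground-truth images at the given b-value.

    Water decays as ``exp(-b * ADC)``; fat is left unattenuated (its apparent
    diffusion attenuation is negligible at these b-values).
    """
    water = truth.water * np.exp(-bvalue * truth.adc_map)
    return WaterFatImage(water, truth.fat.copy())


def simulate_acquisition(
    truth: PhantomGroundTruth,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    mode: str = "model_consistent",
    bvalue: float = 0.0,
    noise_sigma: Optional[float] = None,
    seed: Optional[int] = None,
) -> ChemShiftEncodedKSpace:
    """Simulate raw multi-coil k-space data for one b-value.

    ``noise_sigma`` (std of the i.i.d. complex Gaussian k-space noise per
    sampled point, per real/imag channel scaled as sigma/sqrt(2)) defaults to
    the phantom's; the noise stream is seeded deterministically from the
    phantom seed, the b-value and the mode unless ``seed`` is given.
    """
    if mode not in ("model_consistent", "realistic"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    if bvalue not in truth.true_phases:
        raise ValueError(f"no ground-truth phases for b={bvalue}")
    phases = truth.true_phases[bvalue]
    x = attenuated_truth(truth, bvalue)
    ctx = truth.field_context()
    sys = EncodingSystem(ctx, phases, traj, spectrum)
    if mode == "model_consistent":
        data = sys.forward(x)
    else:
        data = _forward_realistic(sys, x)
    sigma = truth.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        if seed is None:
            seed = (truth.seed * 1000003 + int(bvalue) * 97 + (mode == "realistic")) % (
                2**31 - 1
            )
        rng = np.random.default_rng(seed)
        noise = sigma / np.sqrt(2) * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        # noise exists only where data were actually sampled
        sampled = traj.shot_masks[None, :, None, :, None]
        data = data + noise * sampled
    return ChemShiftEncodedKSpace(data, traj, bvalue=bvalue)


def _forward_realistic(sys: EncodingSystem, x: WaterFatImage) -> np.ndarray:
    """Forward model with full per-line B0 dephasing exp(-i 2 pi psiB t)."""
    traj, ctx = sys.traj, sys.ctx
    N, L, J = traj.num_encodings, traj.num_shots, ctx.num_coils
    t = traj.line_times
    b0 = ctx.b0_map
    out = np.zeros((N, L, J) + traj.matrix, complex)
    for n in range(N):
        for l in range(L):
            ph = sys.b0_phase[n] * sys.shot_phase[n, l]
            wimg = ctx.csm_water * (x.water * ph)[None]
            fimg = ctx.csm_fat * (x.fat * ph)[None]
            for ky in traj.shot_lines(l):
                extra = np.exp(-2j * np.pi * b0 * t[ky])[None]
                kline = fft2c(wimg * extra)[:, ky, :] + sys.fat_weights[n, ky] * fft2c(
                    fimg * extra
                )[:, ky, :]
                out[n, l, :, ky, :] = kline
    return out
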