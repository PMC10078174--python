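"""Linear water/fat separation and the water-fat MUSE initializer.

``solve_water_fat`` solves the shot-combined least-squares problem
``min_X ||A X - S||^2`` by conjugate gradients on the normal equations, with
the motion phase maps held fixed. ``water_fat_muse`` treats every
(encoding, shot) dataset as an independent undersampled SENSE-type water/fat
problem (no B0 and no motion-phase operator), optionally with isotropic
total-variation regularization solved by iteratively reweighted least squares;
the per-shot solutions feed the merged-phase extraction and the b=0 phase
subtraction that initialize the self-navigated reconstruction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

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
from .linalg import CGResult, conjugate_gradient


def _pack_wf(x: WaterFatImage) -> np.ndarray:
    return np.stack([x.water, x.fat])


def _unpack_wf(v: np.ndarray) -> WaterFatImage:
    return WaterFatImage(v[0], v[1])


def solve_water_fat(
    s: ChemShiftEncodedKSpace,
    ctx: FieldContext,
    phases: ShotPhaseMaps,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    cg_tol: float = 1e-3,
    cg_maxiter: int = 20,
    x0: Optional[WaterFatImage] = None,
) -> Tuple[WaterFatImage, CGResult]:
    """Solve the water/fat least-squares problem for fixed phase maps.

    Conjugate gradients on the normal equations ``A^H A X = A^H S``; stops
    when the normalized residual norm drops below ``cg_tol`` or after
    ``cg_maxiter`` iterations. Returns the solution together with the CG
    diagnostics (residual history, convergence/breakdown flags).
    """
    sys = EncodingSystem(ctx, phases, traj, spectrum)
    rhs = _pack_wf(sys.adjoint(s.data))

    def matvec(v):
        return _pack_wf(sys.normal(_unpack_wf(v)))

    res = conjugate_gradient(
        matvec,
        rhs,
        x0=None if x0 is None else _pack_wf(x0),
        tol=cg_tol,
        maxiter=cg_maxiter,
    )
    if res.breakdown:
        warnings.warn(
            "CG breakdown (non-positive curvature) in solve_water_fat; "
            "returning best iterate",
            RuntimeWarning,
        )
    return _unpack_wf(res.x), res


@dataclass
class ShotWaterFat:
    """Per-(encoding, shot) water/fat estimates from water-fat MUSE."""

    water: np.ndarray  # (N, L, Npe, Nfe) complex
    fat: np.ndarray

    def image(self, n: int, l: int) -> WaterFatImage:
        return WaterFatImage(self.water[n, l], self.fat[n, l])


def _grad(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Periodic forward differences along both image axes."""
    return x - np.roll(x, 1, axis=-2), x - np.roll(x, 1, axis=-1)


def _grad_adj(gy: np.ndarray, gx: np.ndarray) -> np.ndarray:
    return (gy - np.roll(gy, -1, axis=-2)) + (gx - np.roll(gx, -1, axis=-1))


def water_fat_muse(
    s: ChemShiftEncodedKSpace,
    ctx: FieldContext,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    lambda_tv: float = 0.01,
    cg_tol: float = 1e-2,
    cg_maxiter: int = 10,
    irls_iters: int = 3,
) -> ShotWaterFat:
    """Independent per-(encoding, shot) SENSE-type water/fat reconstructions.

    Each shot's lines form an L-fold undersampled system in which only the
    coil sensitivities (with water/fat masks, if set) and the per-line fat
    modulation encode; B0 and motion-phase operators are dropped. Isotropic
    eps-smoothed total variation (weight ``lambda_tv``) regularizes each
    water/fat image separately via IRLS, every inner system solved by CG.
    With ``lambda_tv = 0`` the unregularized (minimum-norm) least-squares
    solution is returned.
    """
    N, L, J = traj.num_encodings, traj.num_shots, ctx.num_coils
    if J * 1.0 / L < 2.0 and lambda_tv == 0:
        warnings.warn(
            f"per-shot water/fat system is underdetermined (J={J}, L={L}); "
            "returning minimum-norm solution",
            RuntimeWarning,
        )
    sys = EncodingSystem(
        ctx,
        ShotPhaseMaps.zeros(N, L, traj.matrix),
        traj,
        spectrum,
        use_b0=False,
        use_shot_phases=False,
    )
    water = np.zeros((N, L) + traj.matrix, complex)
    fat = np.zeros_like(water)
    for n in range(N):
        for l in range(L):
            rhs = np.stack(sys.decode_nl(s.data[n, l], n, l))

            def normal(v, n=n, l=l):
                k = sys.encode_nl(v[0], v[1], n, l)
                return np.stack(sys.decode_nl(k, n, l))

            if lambda_tv == 0:
                res = conjugate_gradient(normal, rhs, tol=cg_tol, maxiter=cg_maxiter)
                x = res.x
            else:
                x = np.zeros_like(rhs)
                scale = float(np.abs(rhs).max()) or 1.0
                eps = 1e-6 * scale
                for _ in range(irls_iters):
                    gy, gx = _grad(x)
                    w = 1.0 / np.sqrt(np.abs(gy) ** 2 + np.abs(gx) ** 2 + eps**2)

                    def reg_normal(v, w=w, normal=normal):
                        gy, gx = _grad(v)
                        return normal(v) + lambda_tv * _grad_adj(w * gy, w * gx)

                    res = conjugate_gradient(
                        reg_normal, rhs, x0=x, tol=cg_tol, maxiter=cg_maxiter
                    )
                    x = res.x
            water[n, l], fat[n, l] = x[0], x[1]
    return ShotWaterFat(water=water, fat=fat)


def merged_phase(
    wf: ShotWaterFat,
    water_weight: float = 1.0,
    fat_weight: float = 1.0,
    zero_threshold: float = 1e-8,
) -> ShotPhaseMaps:
    """Phase of the weighted water+fat sum, per (encoding, shot).

    Voxels whose summed magnitude is below ``zero_threshold`` times the
    per-map maximum get phase zero instead of the noise-dominated angle.
    """
    merged = water_weight * wf.water + fat_weight * wf.fat
    phases = np.angle(merged)
    mag = np.abs(merged)
    peak = mag.max(axis=(-2, -1), keepdims=True)
    phases[mag < zero_threshold * np.maximum(peak, 1e-300)] = 0.0
    return ShotPhaseMaps(phases)


def init_diffusion_phase(
    phase_b: ShotPhaseMaps, phase_b0: ShotPhaseMaps
) -> ShotPhaseMaps:
    """Wrap-safe subtraction of the b=0 base phase from the DW merged phase.

    Computed as ``angle(exp(i (phi_b - phi_b0)))`` so the result always lies
    in (-pi, pi]; this isolates the pure motion-induced diffusion phase.
    """
    if phase_b.shape != phase_b0.shape:
        raise ValueError("phase map shapes disagree")
    diff = np.angle(np.exp(1j * (phase_b.phases - phase_b0.phases)))
    return ShotPhaseMaps(diff)
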