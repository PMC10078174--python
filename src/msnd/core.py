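"""Self-navigated joint water/fat and shot-phase estimation (Gauss-Newton).

The reconstruction alternates, per Gauss-Newton iteration:

1. solve the linear water/fat problem for the current phase maps;
2. linearize the motion-phase term ``e^{-i phi}(1 - i d_phi)`` and solve the
   mixed complex/real least-squares system for the image and phase updates
   (conjugate gradients on the real-augmented normal equations);
3. add the phase update and enforce smoothness of each ``e^{i phi_{n,l}}`` by
   triangular-window filtering in k-space;
4. re-solve the water/fat problem with the updated phases and track the
   normalized data residual ``||S - A X|| / ||S||``.

The loop stops when the residual falls below the tolerance, the iteration
budget is exhausted, or an iteration fails to decrease the residual (the best
iterate is kept — the residual history over accepted iterations is therefore
non-increasing). A global phase constant shared by all phase maps is a gauge
freedom of the model (it trades against a global rotation of the images), so
recovered phases are only meaningful up to one constant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

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
from .linalg import conjugate_gradient, fft2c, ifft2c, triangular_window_2d
from .separation import (
    init_diffusion_phase,
    merged_phase,
    solve_water_fat,
    water_fat_muse,
)


@dataclass
class ReconConfig:
    """Tunable parameters of the self-navigated reconstruction.

    Defaults follow the settings used throughout: Gauss-Newton tolerance 1e-4
    with at most 8 iterations; CG tolerance 1e-3 / 20 iterations for the main
    linear systems and 1e-2 / 10 iterations for the MUSE initializer with
    TV weight 0.01; triangular-window full width 5/7 of the matrix; water/fat
    mask threshold 0.03 of the maximum magnitude with one erosion and three
    dilation iterations.
    """

    gn_tol: float = 1e-4
    gn_maxiter: int = 8
    cg_tol_main: float = 1e-3
    cg_maxiter_main: int = 20
    cg_tol_init: float = 1e-2
    cg_maxiter_init: int = 10
    lambda_tv: float = 0.01
    window_fraction: float = 5.0 / 7.0
    mask_threshold: float = 0.03
    erosion_iters: int = 1
    dilation_iters: int = 3
    convergence_metric: str = "data_residual"  # or "update_norm"
    phase_smoothing_weighting: str = "magnitude"  # or "uniform"
    seed: int = 0

    def __post_init__(self):
        for name in ("gn_tol", "cg_tol_main", "cg_tol_init"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.window_fraction <= 1.0:
            raise ValueError("window_fraction must be in (0, 1]")


@dataclass
class GaussNewtonState:
    """State carried across Gauss-Newton iterations."""

    image: WaterFatImage
    phases: ShotPhaseMaps
    iteration: int = 0
    residuals: list = field(default_factory=list)
    converged: bool = False
    stalled: bool = False


def smooth_phase(
    phases: ShotPhaseMaps,
    window_fraction: float,
    weights: Optional[np.ndarray] = None,
) -> ShotPhaseMaps:
    """Enforce smoothness of each phase map via its phasor.

    For each (encoding, shot): ``phi <- angle(IFFT(FFT(m e^{i phi}) . W))``
    where ``W`` is the centered separable 2D triangular window of full width
    ``window_fraction`` times the matrix size (peak 1 at DC, so constant maps
    are unchanged) and ``m`` is an optional nonnegative weight image (e.g.
    the current water+fat magnitude; broadcastable to the phase-map stack).
    Weighting by the signal magnitude keeps the meaningless background phase
    from bleeding across the object edge; with ``weights=None`` the unit
    phasor is filtered.
    """
    w = triangular_window_2d(phases.shape[2:], window_fraction)
    phasor = np.exp(1j * phases.phases)
    if weights is not None:
        phasor = np.broadcast_to(np.asarray(weights, float), phases.shape) * phasor
    smoothed = ifft2c(fft2c(phasor) * w)
    return ShotPhaseMaps(np.angle(smoothed))


# ---------------------------------------------------------------------------
# real-augmented Gauss-Newton linear system
# ---------------------------------------------------------------------------
def _pack(dw: np.ndarray, df: np.ndarray, dphi: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [dw.real.ravel(), dw.imag.ravel(), df.real.ravel(), df.imag.ravel(), dphi.ravel()]
    )


def _unpack(v: np.ndarray, grid, phi_shape):
    q = int(np.prod(grid))
    dw = (v[:q] + 1j * v[q : 2 * q]).reshape(grid)
    df = (v[2 * q : 3 * q] + 1j * v[3 * q : 4 * q]).reshape(grid)
    dphi = v[4 * q :].reshape(phi_shape)
    return dw, df, dphi


class GaussNewtonJacobian:
    """Matrix-free Jacobian B of the linearized model at (X, Phi).

    ``B (dW, dF, dPhi)`` applies the frozen system A to the per-(n, l) channel
    inputs ``(dW - i W dPhi_{n,l}, dF - i F dPhi_{n,l})``; phase unknowns are
    real-valued, image updates complex.
    """

    def __init__(self, sys: EncodingSystem, image: WaterFatImage):
        self.sys = sys
        self.image = image
        traj = sys.traj
        self.grid = traj.matrix
        self.phi_shape = (traj.num_encodings, traj.num_shots) + traj.matrix

    def apply(self, dw, df, dphi) -> np.ndarray:
        traj = self.sys.traj
        N, L = traj.num_encodings, traj.num_shots
        J = self.sys.ctx.num_coils
        out = np.zeros((N, L, J) + self.grid, complex)
        w, f = self.image.water, self.image.fat
        for n in range(N):
            for l in range(L):
                wimg = dw - 1j * w * dphi[n, l]
                fimg = df - 1j * f * dphi[n, l]
                out[n, l] = self.sys.encode_nl(wimg, fimg, n, l)
        return out

    def apply_adjoint(self, data: np.ndarray):
        traj = self.sys.traj
        N, L = traj.num_encodings, traj.num_shots
        w, f = self.image.water, self.image.fat
        dw = np.zeros(self.grid, complex)
        df = np.zeros(self.grid, complex)
        dphi = np.zeros(self.phi_shape)
        for n in range(N):
            for l in range(L):
                gw, gf = self.sys.decode_nl(data[n, l], n, l)
                dw += gw
                df += gf
                dphi[n, l] = (1j * np.conj(w) * gw + 1j * np.conj(f) * gf).real
        return dw, df, dphi

    def solve(self, delta_s: np.ndarray, tol: float, maxiter: int):
        """Least-squares solve of ``min ||B dY - dS||`` by real-augmented CG."""
        rhs = _pack(*self.apply_adjoint(delta_s))

        def matvec(v):
            dw, df, dphi = _unpack(v, self.grid, self.phi_shape)
            return _pack(*self.apply_adjoint(self.apply(dw, df, dphi)))

        res = conjugate_gradient(matvec, rhs, tol=tol, maxiter=maxiter)
        return _unpack(res.x, self.grid, self.phi_shape), res


def gn_update(
    state: GaussNewtonState,
    s: ChemShiftEncodedKSpace,
    ctx: FieldContext,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    cfg: ReconConfig,
) -> GaussNewtonState:
    """One Gauss-Newton iteration: phase update, smoothing, water/fat re-solve.

    The returned state carries the updated phases and images and an appended
    normalized data residual; a non-finite residual aborts with an error.
    """
    sys = EncodingSystem(ctx, state.phases, traj, spectrum)
    delta_s = s.data - sys.forward(state.image)
    jac = GaussNewtonJacobian(sys, state.image)
    (dw, df, dphi), _ = jac.solve(delta_s, cfg.cg_tol_main, cfg.cg_maxiter_main)
    new_phases = ShotPhaseMaps(state.phases.phases + dphi)
    weights = None
    if cfg.phase_smoothing_weighting == "magnitude":
        weights = np.abs(state.image.water) + np.abs(state.image.fat)
    new_phases = smooth_phase(new_phases, cfg.window_fraction, weights=weights)
    image, _ = solve_water_fat(
        s,
        ctx,
        new_phases,
        traj,
        spectrum,
        cg_tol=cfg.cg_tol_main,
        cg_maxiter=cfg.cg_maxiter_main,
        x0=state.image,
    )
    residual = _data_residual(s, ctx, new_phases, traj, spectrum, image)
    if not np.isfinite(residual):
        raise FloatingPointError("non-finite Gauss-Newton residual")
    new_state = GaussNewtonState(
        image=image,
        phases=new_phases,
        iteration=state.iteration + 1,
        residuals=state.residuals + [residual],
    )
    if cfg.convergence_metric == "update_norm":
        upd = float(np.linalg.norm(dphi)) / max(
            1e-300, float(np.linalg.norm(new_phases.phases)) or 1.0
        )
        new_state.converged = upd < cfg.gn_tol
    else:
        new_state.converged = residual < cfg.gn_tol
    return new_state


def _data_residual(s, ctx, phases, traj, spectrum, image) -> float:
    sys = EncodingSystem(ctx, phases, traj, spectrum)
    return float(np.linalg.norm(s.data - sys.forward(image)) / np.linalg.norm(s.data))


def msnd_reconstruct(
    s: ChemShiftEncodedKSpace,
    ctx: FieldContext,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    cfg: Optional[ReconConfig] = None,
    init: str = "zero",
    s_b0: Optional[ChemShiftEncodedKSpace] = None,
) -> Tuple[WaterFatImage, ShotPhaseMaps, Dict]:
    """Self-navigated water/fat reconstruction of one (b-value, direction).

    ``init="zero"`` starts from zero phase maps; ``init="muse"`` runs the
    per-shot water-fat MUSE reconstruction on the DW data (and, when ``s_b0``
    is given, on the b=0 data whose merged phase is subtracted wrap-safely) to
    form the initial phase maps. Returns the final water/fat image, the final
    shot phase maps, and a diagnostics dict with the residual history.
    """
    cfg = cfg or ReconConfig()
    N, L = traj.num_encodings, traj.num_shots
    if init == "zero":
        phases = ShotPhaseMaps.zeros(N, L, traj.matrix)
    elif init == "muse":
        wf = water_fat_muse(
            s,
            ctx,
            traj,
            spectrum,
            lambda_tv=cfg.lambda_tv,
            cg_tol=cfg.cg_tol_init,
            cg_maxiter=cfg.cg_maxiter_init,
        )
        phases = merged_phase(wf)
        if s_b0 is not None:
            wf0 = water_fat_muse(
                s_b0,
                ctx,
                traj,
                spectrum,
                lambda_tv=cfg.lambda_tv,
                cg_tol=cfg.cg_tol_init,
                cg_maxiter=cfg.cg_maxiter_init,
            )
            phases = init_diffusion_phase(phases, merged_phase(wf0))
        init_weights = None
        if cfg.phase_smoothing_weighting == "magnitude":
            init_weights = np.abs(wf.water) + np.abs(wf.fat)  # per-(n, l) magnitudes
        phases = smooth_phase(phases, cfg.window_fraction, weights=init_weights)
    else:
        raise ValueError(f"unknown init {init!r}")

    image, _ = solve_water_fat(
        s, ctx, phases, traj, spectrum, cg_tol=cfg.cg_tol_main, cg_maxiter=cfg.cg_maxiter_main
    )
    state = GaussNewtonState(image=image, phases=phases)
    state.residuals.append(_data_residual(s, ctx, phases, traj, spectrum, image))
    best = state
    for _ in range(cfg.gn_maxiter):
        if state.converged:
            break
        new_state = gn_update(state, s, ctx, traj, spectrum, cfg)
        if new_state.residuals[-1] > best.residuals[-1] + 1e-12:
            # rejected: keep the best iterate, stop (monotone accepted history)
            best.stalled = True
            state = best
            break
        state = new_state
        best = new_state
    diagnostics = {
        "residuals": state.residuals,
        "iterations": state.iteration,
        "converged": state.converged,
        "stalled": state.stalled,
        "init": init,
    }
    return state.image, state.phases, diagnostics
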