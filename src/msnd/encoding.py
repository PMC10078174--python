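"""Linear signal model for chemical-shift-encoded diffusion-weighted ms-EPI.

The acquisition model, per encoding ``n``, shot ``l`` and coil ``j``, is

    s_{n,l,j} = K_l F [ c_j (rho_w + w_n(t) * rho_f) e^{-i 2 pi psiB dTE_n} e^{-i phi_{n,l}} ]

where ``K_l`` samples the interleaved phase-encode lines of shot ``l``, ``F``
is the centered orthonormal 2D Fourier transform, ``w_n`` is the multi-peak
fat modulation weight evaluated at ``dTE_n + t(line)`` (a per-line k-space
scaling, which is what displaces fat along the phase-encode direction),
``psiB`` is the B0 off-resonance map in Hz (applied only through the
encoding-shift phase, the model's stated approximation), and ``phi_{n,l}`` is
the real-valued motion-induced shot phase map.

``EncodingSystem`` bundles the operator ingredients and exposes the forward
map, its exact adjoint, and per-(n, l) variants used by the Gauss-Newton
self-navigation loop and the per-shot MUSE initializer.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fat_model import FatSpectrum, fat_modulation_weight
from .linalg import fft2c, ifft2c


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class EPITrajectory:
    """Interleaved multishot EPI sampling geometry.

    Shot ``l`` acquires phase-encode lines ``l, l+L, l+2L, ...`` in ascending
    order, one line every ``echo_spacing`` seconds; the line closest to the
    k-space center is assigned time zero (spin-echo center). The effective
    time per unit phase-encode step is therefore ``echo_spacing / num_shots``.
    """

    matrix: tuple
    num_shots: int
    delta_te: tuple
    echo_spacing: float

    def __post_init__(self):
        object.__setattr__(self, "matrix", tuple(int(v) for v in self.matrix))
        object.__setattr__(self, "delta_te", tuple(float(v) for v in self.delta_te))
        npe, nfe = self.matrix
        if npe < 1 or nfe < 1 or self.num_shots < 1:
            raise ValueError("degenerate trajectory geometry")
        if self.num_shots > npe:
            raise ValueError("more shots than phase-encode lines")
        if self.echo_spacing <= 0:
            raise ValueError("echo spacing must be positive")

    @property
    def num_encodings(self) -> int:
        return len(self.delta_te)

    @property
    def effective_dwell(self) -> float:
        """Effective time per unit phase-encode step (s)."""
        return self.echo_spacing / self.num_shots

    def shot_lines(self, shot: int) -> np.ndarray:
        """Ascending phase-encode line indices acquired by ``shot``."""
        return np.arange(shot, self.matrix[0], self.num_shots)

    @property
    def shot_masks(self) -> np.ndarray:
        """Boolean (L, Npe) array marking the lines each shot acquires."""
        npe = self.matrix[0]
        masks = np.zeros((self.num_shots, npe), dtype=bool)
        for l in range(self.num_shots):
            masks[l, self.shot_lines(l)] = True
        return masks

    @property
    def line_times(self) -> np.ndarray:
        """Time (s) of each phase-encode line relative to the spin echo.

        Interleaved ms-EPI staggers each shot's readout window by
        ``echo_spacing * l / L`` so that the time of line ``ky`` is linear
        across the combined k-space, ``(ky - Npe//2) * echo_spacing / L``;
        within each shot, times are then affine in acquisition order with
        slope ``echo_spacing``, and the line nearest the k-space center is
        the one closest to the spin echo.
        """
        npe = self.matrix[0]
        return (np.arange(npe) - npe // 2) * self.effective_dwell


@dataclass
class FieldContext:
    """Field and receive-chain context: B0 map, coil sensitivities, masks.

    ``water_mask``/``fat_mask`` (binary, optional) restrict the support of the
    water/fat channels by multiplying into the coil-sensitivity operator.
    """

    b0_map: np.ndarray
    csm: np.ndarray
    water_mask: Optional[np.ndarray] = None
    fat_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.b0_map = np.asarray(self.b0_map, dtype=float)
        self.csm = np.asarray(self.csm, dtype=complex)
        if self.csm.ndim != 3 or self.csm.shape[0] < 1:
            raise ValueError("csm must be (num_coils, Npe, Nfe) with >= 1 coil")
        if self.csm.shape[1:] != self.b0_map.shape:
            raise ValueError("csm and b0 map grids disagree")
        for name in ("water_mask", "fat_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m)
                if m.shape != self.b0_map.shape:
                    raise ValueError(f"{name} grid disagrees with b0 map")
                if not np.all(np.isin(m, (0, 1))):
                    raise ValueError(f"{name} must be binary")
                setattr(self, name, m.astype(float))

    @property
    def num_coils(self) -> int:
        return self.csm.shape[0]

    @property
    def grid(self) -> tuple:
        return self.b0_map.shape

    @property
    def csm_water(self) -> np.ndarray:
        if self.water_mask is None:
            return self.csm
        return self.csm * self.water_mask

    @property
    def csm_fat(self) -> np.ndarray:
        if self.fat_mask is None:
            return self.csm
        return self.csm * self.fat_mask


@dataclass
class ShotPhaseMaps:
    """Real motion-induced phase images phi_{n,l} on the image grid (rad)."""

    phases: np.ndarray  # (N, L, Npe, Nfe), real

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 4:
            raise ValueError("phases must be (N, L, Npe, Nfe)")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phase maps must be finite")

    @classmethod
    def zeros(cls, num_encodings, num_shots, grid) -> "ShotPhaseMaps":
        return cls(np.zeros((num_encodings, num_shots) + tuple(grid)))

    @property
    def shape(self):
        return self.phases.shape

    def copy(self) -> "ShotPhaseMaps":
        return ShotPhaseMaps(self.phases.copy())


@dataclass
class WaterFatImage:
    """Complex water and fat component images on a common grid."""

    water: np.ndarray
    fat: np.ndarray

    def __post_init__(self):
        self.water = np.asarray(self.water, dtype=complex)
        self.fat = np.asarray(self.fat, dtype=complex)
        if self.water.shape != self.fat.shape:
            raise ValueError("water and fat grids disagree")

    @property
    def grid(self):
        return self.water.shape

    def copy(self) -> "WaterFatImage":
        return WaterFatImage(self.water.copy(), self.fat.copy())


@dataclass
class ChemShiftEncodedKSpace:
    """Raw data tensor S[n, l, j, ky, kx] with its trajectory and b-value.

    Lines not acquired by shot ``l`` are identically zero; the sampling
    pattern itself lives in the trajectory.
    """

    data: np.ndarray
    trajectory: EPITrajectory
    bvalue: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        traj = self.trajectory
        expected = (
            traj.num_encodings,
            traj.num_shots,
            self.data.shape[2] if self.data.ndim == 5 else -1,
        ) + traj.matrix
        if self.data.ndim != 5 or self.data.shape[:2] != expected[:2] or self.data.shape[3:] != traj.matrix:
            raise ValueError(
                f"k-space data shape {self.data.shape} inconsistent with "
                f"(N={traj.num_encodings}, L={traj.num_shots}, J, {traj.matrix})"
            )

    @property
    def num_coils(self) -> int:
        return self.data.shape[2]

    def norm(self) -> float:
        return float(np.linalg.norm(self.data))


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------
class EncodingSystem:
    """The full linear system A for a fixed (context, phases, trajectory, spectrum).

    Precomputes the per-line fat weights, B0 encoding phases and shot sampling
    masks; ``forward``/``adjoint`` act on :class:`WaterFatImage`, and the
    per-(n, l) variants expose the building blocks needed by the Gauss-Newton
    Jacobian and the per-shot MUSE systems.
    """

    def __init__(
        self,
        ctx: FieldContext,
        phases: ShotPhaseMaps,
        traj: EPITrajectory,
        spectrum: FatSpectrum,
        use_b0: bool = True,
        use_shot_phases: bool = True,
    ):
        if ctx.grid != traj.matrix:
            raise ValueError("field context grid disagrees with trajectory matrix")
        if phases.shape[:2] != (traj.num_encodings, traj.num_shots):
            raise ValueError("phase maps inconsistent with (N, L)")
        if phases.shape[2:] != traj.matrix:
            raise ValueError("phase map grid disagrees with trajectory matrix")
        self.ctx = ctx
        self.traj = traj
        self.spectrum = spectrum
        # per-(n, line) fat modulation weight, shape (N, Npe)
        tau = np.asarray(traj.delta_te)[:, None] + traj.line_times[None, :]
        self.fat_weights = fat_modulation_weight(spectrum, tau)
        self.shot_masks = traj.shot_masks
        dte = np.asarray(traj.delta_te)
        if use_b0:
            self.b0_phase = np.exp(-2j * np.pi * ctx.b0_map[None] * dte[:, None, None])
        else:
            self.b0_phase = np.ones((traj.num_encodings,) + traj.matrix, complex)
        if use_shot_phases:
            self.shot_phase = np.exp(-1j * phases.phases)
        else:
            self.shot_phase = np.ones(phases.shape, complex)

    # -- single (n, l) building blocks -------------------------------------
    def encode_nl(self, wimg: np.ndarray, fimg: np.ndarray, n: int, l: int) -> np.ndarray:
        """Encode image-domain water/fat channel inputs into (J, Npe, Nfe) k-space."""
        ph = self.b0_phase[n] * self.shot_phase[n, l]
        kw = fft2c(self.ctx.csm_water * (wimg * ph)[None])
        kf = fft2c(self.ctx.csm_fat * (fimg * ph)[None])
        k = kw + self.fat_weights[n][None, :, None] * kf
        return k * self.shot_masks[l][None, :, None]

    def decode_nl(self, k: np.ndarray, n: int, l: int):
        """Adjoint of :meth:`encode_nl`; returns (water, fat) image gradients."""
        km = k * self.shot_masks[l][None, :, None]
        iw = ifft2c(km)
        ifa = ifft2c(np.conj(self.fat_weights[n])[None, :, None] * km)
        phc = np.conj(self.b0_phase[n] * self.shot_phase[n, l])
        gw = phc * np.sum(np.conj(self.ctx.csm_water) * iw, axis=0)
        gf = phc * np.sum(np.conj(self.ctx.csm_fat) * ifa, axis=0)
        return gw, gf

    # -- full system --------------------------------------------------------
    def forward(self, x: WaterFatImage) -> np.ndarray:
        if x.grid != self.traj.matrix:
            raise ValueError("image grid disagrees with trajectory matrix")
        N, L = self.traj.num_encodings, self.traj.num_shots
        J = self.ctx.num_coils
        out = np.zeros((N, L, J) + self.traj.matrix, complex)
        for n in range(N):
            for l in range(L):
                out[n, l] = self.encode_nl(x.water, x.fat, n, l)
        return out

    def adjoint(self, data: np.ndarray) -> WaterFatImage:
        N, L = self.traj.num_encodings, self.traj.num_shots
        gw = np.zeros(self.traj.matrix, complex)
        gf = np.zeros(self.traj.matrix, complex)
        for n in range(N):
            for l in range(L):
                w, f = self.decode_nl(data[n, l], n, l)
                gw += w
                gf += f
        return WaterFatImage(gw, gf)

    def normal(self, x: WaterFatImage) -> WaterFatImage:
        return self.adjoint(self.forward(x))


def forward_model(
    x: WaterFatImage,
    ctx: FieldContext,
    phases: ShotPhaseMaps,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
) -> ChemShiftEncodedKSpace:
    """Apply the full forward model A to a water/fat image pair."""
    sys = EncodingSystem(ctx, phases, traj, spectrum)
    return ChemShiftEncodedKSpace(sys.forward(x), traj)


def adjoint_model(
    s: ChemShiftEncodedKSpace,
    ctx: FieldContext,
    phases: ShotPhaseMaps,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
) -> WaterFatImage:
    """Apply the exact adjoint of :func:`forward_model`."""
    sys = EncodingSystem(ctx, phases, traj, spectrum)
    return sys.adjoint(s.data)


def apply_masks_to_csm(
    ctx: FieldContext, water_mask: np.ndarray, fat_mask: np.ndarray
) -> FieldContext:
    """Return a context whose water/fat coil-sensitivity channels are masked.

    The binary masks multiply into the coil-sensitivity weighting operator for
    the respective species, restricting each channel's support.
    """
    return FieldContext(
        b0_map=ctx.b0_map, csm=ctx.csm, water_mask=water_mask, fat_mask=fat_mask
    )
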