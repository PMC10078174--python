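"""Calibration from non-diffusion (b=0) data and geometric distortion handling.

The b=0 acquisition carries no motion-induced shot phases (diffusion
gradients are off), so its phase structure encodes only B0 off-resonance and
the fat chemical shift. This module estimates the B0 map and b=0 water/fat
images by a Gauss-Newton scheme (VARPRO-style per-voxel frequency search for
initialization, then k-space refinement), derives binary water/fat masks by
thresholding and morphology, calibrates prescan coil-sensitivity maps to the
EPI-distorted geometry (inverse conjugate-phase distortion), offers a simple
smoothed-ratio CSM autocalibration with fat-position correction, and performs
the conjugate-phase (CPR) geometric distortion correction used in
post-processing.
"""
from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import ReconConfig
from .encoding import (
    ChemShiftEncodedKSpace,
    EncodingSystem,
    EPITrajectory,
    FieldContext,
    ShotPhaseMaps,
    WaterFatImage,
)
from .fat_model import FatSpectrum, fat_modulation_weight
from .linalg import conjugate_gradient, fft2c, ifft2c, triangular_window_2d
from .separation import solve_water_fat


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------
def make_masks(
    wf_b0: WaterFatImage,
    threshold: float = 0.03,
    erosion_iters: int = 1,
    dilation_iters: int = 3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Binary water/fat masks from the b=0 water/fat magnitudes.

    Each species is thresholded at ``threshold`` times its maximum magnitude,
    then eroded (to drop isolated noise pixels) and dilated (to guard the
    object edge) with a 3x3 cross structuring element. An all-zero image
    yields an empty mask.
    """
    struct = ndimage.generate_binary_structure(2, 1)

    def one(img):
        mag = np.abs(img)
        if mag.max() == 0:
            return np.zeros(mag.shape)
        m = mag > threshold * mag.max()
        if erosion_iters > 0:
            m = ndimage.binary_erosion(m, structure=struct, iterations=erosion_iters)
        if dilation_iters > 0 and m.any():
            m = ndimage.binary_dilation(m, structure=struct, iterations=dilation_iters)
        return m.astype(float)

    return one(wf_b0.water), one(wf_b0.fat)


# ---------------------------------------------------------------------------
# B0 + water/fat estimation from b=0 data
# ---------------------------------------------------------------------------
def _coil_combined_encoded_images(
    s_b0: ChemShiftEncodedKSpace, ctx: FieldContext
) -> np.ndarray:
    """Shot-combined, coil-combined image per encoding, shape (N, Npe, Nfe).

    b=0 data are fully sampled once all shots are merged; the matched-filter
    coil combination uses the supplied sensitivities.
    """
    data = s_b0.data.sum(axis=1)  # (N, J, Npe, Nfe); shots partition k-space
    imgs = ifft2c(data)
    ssq = np.sum(np.abs(ctx.csm) ** 2, axis=0)
    comb = np.sum(np.conj(ctx.csm)[None] * imgs, axis=1) / np.maximum(ssq, 1e-12)[None]
    comb[:, ssq < 1e-12] = 0.0
    return comb


def _varpro_b0_search(
    images: np.ndarray,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    search_hz: float = 500.0,
    num_points: int = 201,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-voxel 1D frequency search minimizing the water/fat fit residual.

    For each candidate psi the demodulated per-encoding signals are fit by the
    two-species model (columns 1 and beta_n, the fat weight at dTE_n); the psi
    with the smallest residual wins. The grid must be fine enough (a few Hz)
    that quantization of the true frequency does not leave a larger residual
    than the multi-peak asymmetry that distinguishes the water/fat-swap branch
    at psi +- the dominant fat offset; this init reduces the risk of falling
    into the swap local minimum.
    """
    dte = np.asarray(traj.delta_te)
    beta = fat_modulation_weight(spectrum, dte)  # (N,)
    G = np.stack([np.ones_like(beta), beta], axis=1)  # (N, 2)
    proj = G @ np.linalg.pinv(G)  # projector onto the species subspace
    resid_op = np.eye(len(dte)) - proj
    candidates = np.linspace(-search_hz, search_hz, num_points)
    d = images.reshape(len(dte), -1)  # (N, Q)
    best_res = np.full(d.shape[1], np.inf)
    best_psi = np.zeros(d.shape[1])
    for psi in candidates:
        demod = d * np.exp(2j * np.pi * psi * dte)[:, None]
        r = np.linalg.norm(resid_op @ demod, axis=0)
        upd = r < best_res
        best_res[upd] = r[upd]
        best_psi[upd] = psi
    dnorm = np.linalg.norm(d, axis=0)
    # fit confidence: voxels whose two-species model fits poorly (e.g. because
    # displaced fat contaminates the image-domain signal there) are downweighted
    confidence = np.clip(1.0 - best_res / np.maximum(dnorm, 1e-300), 0.0, 1.0) ** 2
    return best_psi.reshape(images.shape[1:]), confidence.reshape(images.shape[1:])


class _B0Jacobian:
    """Matrix-free Jacobian for the b=0 Gauss-Newton system.

    The unknown is (dW, dF complex; d_psi real, in Hz); the phase derivative
    scales with the encoding shift: channel inputs per (n, l) are
    ``dW - i 2 pi dTE_n W d_psi`` and likewise for fat.
    """

    def __init__(self, sys: EncodingSystem, image: WaterFatImage):
        self.sys = sys
        self.image = image
        self.grid = sys.traj.matrix
        self.dte = np.asarray(sys.traj.delta_te)

    def apply(self, dw, df, dpsi):
        traj = self.sys.traj
        N, L, J = traj.num_encodings, traj.num_shots, self.sys.ctx.num_coils
        out = np.zeros((N, L, J) + self.grid, complex)
        w, f = self.image.water, self.image.fat
        for n in range(N):
            scale = 2 * np.pi * self.dte[n]
            wimg = dw - 1j * scale * w * dpsi
            fimg = df - 1j * scale * f * dpsi
            for l in range(L):
                out[n, l] = self.sys.encode_nl(wimg, fimg, n, l)
        return out

    def apply_adjoint(self, data):
        traj = self.sys.traj
        N, L = traj.num_encodings, traj.num_shots
        w, f = self.image.water, self.image.fat
        dw = np.zeros(self.grid, complex)
        df = np.zeros(self.grid, complex)
        dpsi = np.zeros(self.grid)
        for n in range(N):
            scale = 2 * np.pi * self.dte[n]
            for l in range(L):
                gw, gf = self.sys.decode_nl(data[n, l], n, l)
                dw += gw
                df += gf
                dpsi += scale * (1j * np.conj(w) * gw + 1j * np.conj(f) * gf).real
        return dw, df, dpsi

    def solve(self, delta_s, tol, maxiter):
        q = int(np.prod(self.grid))

        def pack(dw, df, dpsi):
            return np.concatenate(
                [dw.real.ravel(), dw.imag.ravel(), df.real.ravel(), df.imag.ravel(), dpsi.ravel()]
            )

        def unpack(v):
            dw = (v[:q] + 1j * v[q : 2 * q]).reshape(self.grid)
            df = (v[2 * q : 3 * q] + 1j * v[3 * q : 4 * q]).reshape(self.grid)
            return dw, df, v[4 * q :].reshape(self.grid)

        rhs = pack(*self.apply_adjoint(delta_s))

        def matvec(v):
            return pack(*self.apply_adjoint(self.apply(*unpack(v))))

        res = conjugate_gradient(matvec, rhs, tol=tol, maxiter=maxiter)
        return unpack(res.x)


def _smooth_update(m: np.ndarray, fraction: float, weights: np.ndarray) -> np.ndarray:
    """Normalized-convolution low-pass of a real map.

    The triangular k-space window corresponds to a nonnegative (Fejér-type)
    image-domain kernel, so weighting by the signal magnitude and renormalizing
    is well-posed; it keeps the unconstrained background from diluting the map
    near the object edge.
    """
    w2d = triangular_window_2d(m.shape, fraction)
    num = ifft2c(fft2c((weights * m).astype(complex)) * w2d).real
    den = ifft2c(fft2c(weights.astype(complex)) * w2d).real
    floor = 1e-6 * max(den.max(), 1e-300)
    return num / np.maximum(den, floor)


def estimate_b0_water_fat(
    s_b0: ChemShiftEncodedKSpace,
    ctx: FieldContext,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    cfg: Optional[ReconConfig] = None,
    psi_init: Optional[np.ndarray] = None,
    grid_search: bool = True,
    gn_maxiter: int = 12,
    smooth_iters: int = 6,
    cg_tol: float = 1e-5,
    cg_maxiter: int = 60,
) -> Tuple[np.ndarray, WaterFatImage]:
    """Estimate the B0 map (Hz) and b=0 water/fat images from b=0 k-space.

    Motion phases are zero at b=0, so the only nonlinear unknown is the
    per-voxel off-resonance. Initialization is a coarse per-voxel frequency
    search (+-500 Hz, 21 points) on shot/coil-combined per-encoding images,
    triangular-window smoothed; ``psi_init`` overrides it. The Gauss-Newton
    refinement smooths each frequency *update* with the same triangular
    window (magnitude-weighted normalized convolution) for the first
    ``smooth_iters`` iterations — enforcing the smoothness class while the
    estimate is far from the solution — and then releases the smoothing for
    the remaining masked refinements (band-limiting the accumulated field
    forever would leave window-edge error modes draining at only a few
    percent per iteration). The field-map stage has its own iteration/CG
    budget defaults, independent of the DW loop settings in ``cfg``. Two
    consecutive residual increases abort the loop and return the best
    iterate with a warning.
    """
    cfg = cfg or ReconConfig()
    if traj.num_encodings < 3:
        raise ValueError("B0 + water/fat estimation needs at least 3 encodings")
    images = _coil_combined_encoded_images(s_b0, ctx)
    support_mag = np.sum(np.abs(images), axis=0)
    if psi_init is not None:
        psi = np.asarray(psi_init, dtype=float).copy()
    elif grid_search:
        psi, confidence = _varpro_b0_search(images, traj, spectrum)
        psi[support_mag < 0.05 * support_mag.max()] = 0.0
        psi = ndimage.median_filter(psi, size=5)
        psi = _smooth_update(psi, cfg.window_fraction, support_mag * confidence)
    else:
        psi = np.zeros(traj.matrix)

    zero_phases = ShotPhaseMaps.zeros(traj.num_encodings, traj.num_shots, traj.matrix)
    snorm = np.linalg.norm(s_b0.data)

    def solve_image(psi_map, x0=None):
        ctx_psi = FieldContext(
            b0_map=psi_map, csm=ctx.csm, water_mask=ctx.water_mask, fat_mask=ctx.fat_mask
        )
        image, _ = solve_water_fat(
            s_b0,
            ctx_psi,
            zero_phases,
            traj,
            spectrum,
            cg_tol=cg_tol,
            cg_maxiter=cg_maxiter,
            x0=x0,
        )
        sys = EncodingSystem(ctx_psi, zero_phases, traj, spectrum)
        res = float(np.linalg.norm(s_b0.data - sys.forward(image)) / snorm)
        return image, sys, res

    image, sys, residual = solve_image(psi)
    best = (psi.copy(), image, residual)
    increases = 0
    for it in range(gn_maxiter):
        if residual < cfg.gn_tol:
            break
        delta_s = s_b0.data - sys.forward(image)
        jac = _B0Jacobian(sys, image)
        dw, df, dpsi = jac.solve(delta_s, cg_tol, cg_maxiter)
        # frequency updates are meaningless where there is (almost) no
        # signal; mask them at the usual magnitude threshold and let the
        # normalized convolution extrapolate across those voxels
        weights = np.abs(image.water) + np.abs(image.fat)
        update_mask = weights > cfg.mask_threshold * weights.max()
        if it < smooth_iters:
            psi = psi + _smooth_update(
                dpsi * update_mask, cfg.window_fraction, weights * update_mask
            )
        else:
            psi = psi + dpsi * update_mask
        image, sys, residual = solve_image(psi, x0=image)
        if residual < best[2]:
            best = (psi.copy(), image, residual)
            increases = 0
        else:
            increases += 1
            if increases >= 2:
                warnings.warn(
                    "B0 Gauss-Newton residual increased twice; returning best iterate",
                    RuntimeWarning,
                )
                break
    psi, image, _ = best
    return psi, image


# ---------------------------------------------------------------------------
# CSM calibration and geometric distortion
# ---------------------------------------------------------------------------
def _b0_distort(image: np.ndarray, b0_map: np.ndarray, traj: EPITrajectory) -> np.ndarray:
    """Forward EPI distortion: apply exp(-i 2 pi psiB t(line)) per k-line.

    This is the per-line B0 dephasing an EPI readout imprints on an object;
    naive reconstruction of the result shows the B0-induced phase-encode
    displacement.
    """
    npe = traj.matrix[0]
    t = traj.line_times
    k = np.zeros(image.shape, complex)
    for ky in range(npe):
        mod = image * np.exp(-2j * np.pi * b0_map * t[ky])
        k[ky] = fft2c(mod)[ky]
    return ifft2c(k)


def calibrate_csm_b0(
    prescan_csm: np.ndarray, b0_map: np.ndarray, traj: EPITrajectory
) -> np.ndarray:
    """Resample prescan coil maps into the EPI-distorted geometry.

    Applies the "inverted" geometric distortion (inverse conjugate-phase
    reconstruction) so the coil maps match the distortions of the EPI data
    they will be used to reconstruct; with a zero field map this is the
    identity.
    """
    prescan_csm = np.asarray(prescan_csm, dtype=complex)
    out = np.empty_like(prescan_csm)
    for j in range(prescan_csm.shape[0]):
        out[j] = _b0_distort(prescan_csm[j], b0_map, traj)
    return out


def cpr_correct(image: np.ndarray, b0_map: np.ndarray, traj: EPITrajectory) -> np.ndarray:
    """Conjugate-phase geometric distortion correction (post-processing).

    Demodulates each phase-encode line of the image's k-space by
    ``exp(+i 2 pi psiB(r) t(line))`` voxelwise (explicit per-line sum),
    undoing the B0-induced phase-encode displacement.
    """
    image = np.asarray(image, dtype=complex)
    npe = traj.matrix[0]
    t = traj.line_times
    k = fft2c(image)
    out = np.zeros_like(image)
    for ky in range(npe):
        kline = np.zeros_like(k)
        kline[ky] = k[ky]
        out += ifft2c(kline) * np.exp(2j * np.pi * b0_map * t[ky])
    return out


def apply_b0_pipeline(
    s_b0: ChemShiftEncodedKSpace,
    truth,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    cfg: Optional[ReconConfig] = None,
    csm_source: str = "truth",
    b0_source: str = "auto",
) -> FieldContext:
    """Full b=0 preparation: B0 map, water/fat masks, calibrated masked CSM.

    ``csm_source``/``b0_source`` select between the phantom's ground-truth
    maps ("truth") and estimation from the b=0 data itself ("auto"). Returns
    the field context the DW reconstruction consumes.
    """
    cfg = cfg or ReconConfig()
    if csm_source == "truth":
        csm = truth.csm
    elif csm_source == "auto":
        # need a provisional B0 for the fat-position-corrected composites
        ctx0 = FieldContext(b0_map=np.zeros(traj.matrix), csm=truth.csm)
        b0_prov, _ = estimate_b0_water_fat(s_b0, ctx0, traj, spectrum, cfg)
        csm = autocalibrate_csm(s_b0, traj, spectrum, b0_prov)
    else:
        raise ValueError(f"unknown csm_source {csm_source!r}")
    ctx = FieldContext(b0_map=np.zeros(traj.matrix), csm=csm)
    if b0_source == "auto":
        b0_map, wf_b0 = estimate_b0_water_fat(s_b0, ctx, traj, spectrum, cfg)
    elif b0_source == "truth":
        b0_map = truth.b0_map
        ctx_b0 = FieldContext(b0_map=b0_map, csm=csm)
        zero = ShotPhaseMaps.zeros(traj.num_encodings, traj.num_shots, traj.matrix)
        wf_b0, _ = solve_water_fat(
            s_b0, ctx_b0, zero, traj, spectrum,
            cg_tol=cfg.cg_tol_main, cg_maxiter=cfg.cg_maxiter_main,
        )
    else:
        raise ValueError(f"unknown b0_source {b0_source!r}")
    water_mask, fat_mask = make_masks(
        wf_b0, cfg.mask_threshold, cfg.erosion_iters, cfg.dilation_iters
    )
    return FieldContext(
        b0_map=b0_map, csm=csm, water_mask=water_mask, fat_mask=fat_mask
    )


def autocalibrate_csm(
    s_b0: ChemShiftEncodedKSpace,
    traj: EPITrajectory,
    spectrum: FatSpectrum,
    b0_map: np.ndarray,
    smoothing_sigma: float = 3.0,
    cg_tol: float = 1e-3,
    cg_maxiter: int = 30,
    zero_threshold: float = 1e-3,
) -> np.ndarray:
    """Smoothed-ratio coil-sensitivity autocalibration from b=0 data.

    For each coil the fully sampled (shot-combined) chemical-shift-encoded
    data are separated into water and fat with the known B0 map — removing
    the fat phase-encode displacement — and merged into a composite image.
    Low-pass filtering (Gaussian, ``smoothing_sigma`` pixels) and division by
    the root-sum-of-squares composite yield smooth relative sensitivities;
    voxels without signal get sensitivity zero.
    """
    N, L, J = traj.num_encodings, traj.num_shots, s_b0.num_coils
    zero_phases = ShotPhaseMaps.zeros(N, L, traj.matrix)
    uniform = np.ones((1,) + traj.matrix, complex)
    composites = np.zeros((J,) + traj.matrix, complex)
    for j in range(J):
        ctx_j = FieldContext(b0_map=b0_map, csm=uniform)
        sys = EncodingSystem(ctx_j, zero_phases, traj, spectrum)
        data_j = s_b0.data[:, :, j : j + 1]

        def normal(v, sys=sys):
            k = sys.forward(WaterFatImage(v[0], v[1]))
            out = sys.adjoint(k)
            return np.stack([out.water, out.fat])

        rhs_wf = sys.adjoint(data_j)
        rhs = np.stack([rhs_wf.water, rhs_wf.fat])
        res = conjugate_gradient(normal, rhs, tol=cg_tol, maxiter=cg_maxiter)
        composites[j] = res.x[0] + res.x[1]
    smoothed = ndimage.gaussian_filter(composites.real, sigma=(0, smoothing_sigma, smoothing_sigma)) + 1j * ndimage.gaussian_filter(
        composites.imag, sigma=(0, smoothing_sigma, smoothing_sigma)
    )
    rss = np.sqrt(np.sum(np.abs(smoothed) ** 2, axis=0))
    csm = np.zeros_like(smoothed)
    good = rss > zero_threshold * rss.max()
    csm[:, good] = smoothed[:, good] / rss[good]
    return csm


def csm_alignment_error(
    estimate: np.ndarray, reference: np.ndarray, support: np.ndarray
) -> float:
    """NRMSE between two coil-map sets on support, gauge freedoms removed.

    Coil sensitivities estimated from image data are only defined up to a
    common voxelwise phase (the image phase) and a global complex scale; both
    sets are referenced to their first coil's phase before the scale-aligned
    NRMSE is computed.
    """
    support = np.asarray(support, dtype=bool)

    def referenced(c):
        ref_phase = np.exp(1j * np.angle(c[0]))
        return c * np.conj(ref_phase)[None]

    a = referenced(estimate)[:, support]
    b = referenced(reference)[:, support]
    scale = np.vdot(a, b) / np.vdot(a, a)
    return float(np.linalg.norm(scale * a - b) / np.linalg.norm(b))
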