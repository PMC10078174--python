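"""Shared numerical primitives: centered FFTs, conjugate gradients, k-space windows.

All image-domain arrays follow the (phase-encode, frequency-encode) axis order and
k-space arrays are center-aligned (DC at ``n // 2`` on each axis). The forward
transform uses the e^{-ik.r} kernel with orthonormal scaling, so ``fft2c`` and
``ifft2c`` are exact adjoints/inverses of each other.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


@dataclass
class CGResult:
    """Outcome of a conjugate-gradient solve on the normal equations."""

    x: np.ndarray
    residuals: list = field(default_factory=list)
    converged: bool = False
    breakdown: bool = False
    iterations: int = 0


def conjugate_gradient(matvec, b, x0=None, tol=1e-3, maxiter=20) -> CGResult:
    """Solve ``matvec(x) = b`` for a (real- or complex-valued) Hermitian PSD map.

    The inner product is the real part of the Euclidean one, which makes the
    routine valid both for complex unknowns and for real-augmented systems.
    ``tol`` bounds the residual norm relative to ``||b||``; a non-positive
    curvature direction flags a breakdown and the best iterate is returned.
    """
    b = np.asarray(b)
    x = np.zeros_like(b) if x0 is None else x0.copy()
    r = b - matvec(x) if x0 is not None else b.copy()
    p = r.copy()
    bnorm = float(np.linalg.norm(b))
    res = CGResult(x=x)
    if bnorm == 0.0:
        res.x = np.zeros_like(b)
        res.converged = True
        return res
    rs = float(np.vdot(r, r).real)
    res.residuals.append(np.sqrt(rs) / bnorm)
    for it in range(maxiter):
        if res.residuals[-1] < tol:
            res.converged = True
            break
        ap = matvec(p)
        pap = float(np.vdot(p, ap).real)
        if pap <= 0.0:
            res.breakdown = True
            break
        alpha = rs / pap
        x += alpha * p
        r -= alpha * ap
        rs_new = float(np.vdot(r, r).real)
        res.residuals.append(np.sqrt(rs_new) / bnorm)
        p = r + (rs_new / rs) * p
        rs = rs_new
        res.iterations = it + 1
    else:
        res.converged = res.residuals[-1] < tol
    res.x = x
    return res


def triangular_window_1d(n: int, fraction: float) -> np.ndarray:
    """Centered 1D triangular window, peak 1 at index ``n // 2``.

    ``fraction`` is the full width of the triangle as a fraction of ``n``;
    samples beyond the half-width are zero.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("window fraction must be in (0, 1]")
    half = fraction * n / 2.0
    idx = np.arange(n) - n // 2
    return np.maximum(0.0, 1.0 - np.abs(idx) / half)


def triangular_window_2d(shape, fraction: float) -> np.ndarray:
    """Separable (outer-product) centered 2D triangular window."""
    wy = triangular_window_1d(shape[0], fraction)
    wx = triangular_window_1d(shape[1], fraction)
    return np.outer(wy, wx)


def smooth_real_map(m: np.ndarray, fraction: float) -> np.ndarray:
    """Low-pass a real-valued map by triangular windowing of its k-space."""
    w = triangular_window_2d(m.shape, fraction)
    return ifft2c(fft2c(m.astype(np.complex128)) * w).real
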