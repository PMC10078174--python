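"""Independent brute-force oracles used by the test suite.

These build the encoding physics entry-by-entry from the signal equation
(centered DFT kernel, per-line fat weights, encoding-shift B0 phase, shot
phases) without going through the package's FFT-based operators, so they can
serve as an independent reference for the matrix-free implementations.
"""
import numpy as np


def line_times(traj):
    npe = traj.matrix[0]
    return (np.arange(npe) - npe // 2) * traj.echo_spacing / traj.num_shots


def fat_weight(spectrum, tau):
    amps = np.asarray(spectrum.amplitudes)
    freqs = np.asarray(spectrum.shifts_ppm) * spectrum.field_strength * spectrum.gyromagnetic_ratio
    return np.sum(amps * np.exp(-2j * np.pi * freqs * tau))


def dft_kernel(npe, nfe):
    """Centered 2D DFT kernel K[ky, kx, y, x] with orthonormal scaling."""
    cy, cx = npe // 2, nfe // 2
    ky = np.arange(npe) - cy
    kx = np.arange(nfe) - cx
    y = np.arange(npe) - cy
    x = np.arange(nfe) - cx
    ey = np.exp(-2j * np.pi * np.outer(ky, y) / npe)
    ex = np.exp(-2j * np.pi * np.outer(kx, x) / nfe)
    return np.einsum("ka,lb->klab", ey, ex) / np.sqrt(npe * nfe)


def dense_forward_matrix(traj, spectrum, csm_water, csm_fat, b0, phases):
    """Dense system matrix A: (N*L*J*Npe*Nfe) x (2*Npe*Nfe).

    Rows for lines a shot does not sample are identically zero, mirroring the
    zero-filled k-space container convention.
    """
    npe, nfe = traj.matrix
    N, L = traj.num_encodings, traj.num_shots
    J = csm_water.shape[0]
    t = line_times(traj)
    kern = dft_kernel(npe, nfe)  # (ky, kx, y, x)
    q = npe * nfe
    A = np.zeros((N, L, J, npe, nfe, 2, q), complex)
    for n, dte in enumerate(traj.delta_te):
        b0ph = np.exp(-2j * np.pi * b0 * dte)
        for l in range(L):
            shotph = np.exp(-1j * phases[n, l])
            common = b0ph * shotph
            lines = set(int(v) for v in np.arange(l, npe, L))
            for j in range(J):
                wmap = csm_water[j] * common
                fmap = csm_fat[j] * common
                for ky in range(npe):
                    if ky not in lines:
                        continue
                    wn = fat_weight(spectrum, dte + t[ky])
                    for kx in range(nfe):
                        base = kern[ky, kx]
                        A[n, l, j, ky, kx, 0] = (base * wmap).ravel()
                        A[n, l, j, ky, kx, 1] = wn * (base * fmap).ravel()
    return A.reshape(N * L * J * npe * nfe, 2 * q)


def dense_muse_matrix(traj, spectrum, csm, n, l):
    """Dense per-(encoding, shot) MUSE system (no B0, no shot phases)."""
    npe, nfe = traj.matrix
    J = csm.shape[0]
    t = line_times(traj)
    kern = dft_kernel(npe, nfe)
    q = npe * nfe
    dte = traj.delta_te[n]
    lines = set(int(v) for v in np.arange(l, npe, traj.num_shots))
    A = np.zeros((J, npe, nfe, 2, q), complex)
    for j in range(J):
        for ky in range(npe):
            if ky not in lines:
                continue
            wn = fat_weight(spectrum, dte + t[ky])
            for kx in range(nfe):
                base = kern[ky, kx]
                A[j, ky, kx, 0] = (base * csm[j]).ravel()
                A[j, ky, kx, 1] = wn * (base * csm[j]).ravel()
    return A.reshape(J * npe * nfe, 2 * q)


def subpixel_shift_pe(image, reference):
    """Sub-pixel phase-encode displacement of ``image`` w.r.t. ``reference``.

    Estimated from the phase slope of the cross-power spectrum along the
    phase-encode axis (robust linear fit over well-conditioned samples).
    """
    F1 = np.fft.fft2(np.asarray(image))
    F2 = np.fft.fft2(np.asarray(reference))
    cross = F1 * np.conj(F2)
    npe = image.shape[0]
    # collapse the frequency-encode axis, use low PE frequencies only
    prof = cross.sum(axis=1)
    ky = np.fft.fftfreq(npe)
    sel = np.abs(ky) <= 0.25
    order = np.argsort(ky[sel])
    freqs = ky[sel][order]
    phase = np.unwrap(np.angle(prof[sel][order]))
    slope = np.polyfit(freqs, phase, 1)[0]
    return -slope / (2 * np.pi)
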