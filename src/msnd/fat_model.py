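"""Multi-peak fat spectral model.

Fat protons resonate at several chemical shifts below (and one slightly above)
the water line. In a chemical-shift-encoded EPI acquisition each k-space sample
at time ``tau = dTE_n + t`` sees the fat magnetization multiplied by the complex
weight ``sum_m alpha_m * exp(-i 2 pi psi_m tau)``, where ``alpha_m`` are the
normalized relative peak amplitudes and ``psi_m`` the peak frequency offsets in
hertz. Because the chemical shift is spatially invariant, this weight factors
out of the Fourier integral and the whole fat off-resonance effect becomes a
per-sample (per-EPI-line) scaling of the fat channel's k-space data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import yaml

#: Gyromagnetic ratio of the proton in MHz per tesla.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577

# Literature six-peak triglyceride table (ppm offsets relative to water and
# relative amplitudes); the dominant methylene peak sits at -3.40 ppm, which is
# -434 Hz at 3 T. Amplitudes are renormalized to sum to one on construction.
SIX_PEAK_SHIFTS_PPM = (-3.80, -3.40, -2.60, -1.94, -0.39, 0.60)
SIX_PEAK_AMPLITUDES = (0.087, 0.693, 0.128, 0.004, 0.039, 0.048)


@dataclass(frozen=True)
class FatSpectrum:
    """An M-peak fat model tied to a main field strength.

    Parameters
    ----------
    shifts_ppm:
        Chemical shifts of the peaks relative to water, in ppm (negative for
        the bulk of the fat spectrum).
    amplitudes:
        Nonnegative relative amplitudes, summing to one.
    field_strength:
        Main magnetic field in tesla.
    gyromagnetic_ratio:
        In MHz/T; fixed default 42.577.
    """

    shifts_ppm: tuple
    amplitudes: tuple
    field_strength: float
    gyromagnetic_ratio: float = GYROMAGNETIC_RATIO_MHZ_PER_T

    def __post_init__(self):
        object.__setattr__(self, "shifts_ppm", tuple(float(s) for s in self.shifts_ppm))
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        if len(self.shifts_ppm) != len(self.amplitudes) or len(self.shifts_ppm) < 1:
            raise ValueError("need M >= 1 peaks with matching shifts and amplitudes")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("peak amplitudes must be nonnegative")
        if abs(sum(self.amplitudes) - 1.0) > 1e-12:
            raise ValueError("peak amplitudes must sum to 1 (within 1e-12)")
        if self.field_strength <= 0:
            raise ValueError("field strength must be positive")

    @property
    def num_peaks(self) -> int:
        return len(self.shifts_ppm)

    @property
    def frequencies_hz(self) -> np.ndarray:
        """Peak frequency offsets psi_m in Hz: ppm x B0[T] x gamma[MHz/T]."""
        return (
            np.asarray(self.shifts_ppm)
            * self.field_strength
            * self.gyromagnetic_ratio
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "shifts_ppm": list(self.shifts_ppm),
            "amplitudes": list(self.amplitudes),
            "field_T": self.field_strength,
            "gyromagnetic_ratio_MHz_per_T": self.gyromagnetic_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FatSpectrum":
        return cls(
            shifts_ppm=tuple(d["shifts_ppm"]),
            amplitudes=tuple(d["amplitudes"]),
            field_strength=float(d["field_T"]),
            gyromagnetic_ratio=float(
                d.get("gyromagnetic_ratio_MHz_per_T", GYROMAGNETIC_RATIO_MHZ_PER_T)
            ),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "FatSpectrum":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def single_peak(cls, frequency_hz: float, field_strength: float = 3.0) -> "FatSpectrum":
        """Single-resonance model with the given absolute offset in Hz."""
        ppm = frequency_hz / (field_strength * GYROMAGNETIC_RATIO_MHZ_PER_T)
        return cls(shifts_ppm=(ppm,), amplitudes=(1.0,), field_strength=field_strength)


def fat_modulation_weight(spectrum: FatSpectrum, tau) -> np.ndarray:
    """Complex fat phase-modulation weight at sample time ``tau`` (seconds).

    ``sum_m alpha_m exp(-i 2 pi psi_m tau)``; magnitude is bounded by one
    because the amplitudes are normalized. ``tau`` may be a scalar or array.
    """
    tau = np.asarray(tau, dtype=float)
    amps = np.asarray(spectrum.amplitudes)
    freqs = spectrum.frequencies_hz
    w = np.sum(
        amps * np.exp(-2j * np.pi * freqs * tau[..., None]), axis=-1
    )
    return w if w.ndim else complex(w)


def default_six_peak_model(
    field_strength: float,
    reference_te: float | None = None,
    amplitude_reweighting: Callable[[Sequence[float], Sequence[float], float], Sequence[float]] | None = None,
) -> FatSpectrum:
    """Standard six-peak fat model at the given field strength.

    ``amplitude_reweighting(shifts_ppm, amplitudes, reference_te)`` is an
    optional hook that can re-weight the peak amplitudes for a given reference
    echo time (e.g. to fold relaxation effects into effective weights); it
    defaults to the identity. The returned amplitudes are renormalized to sum
    to one.
    """
    amps = np.asarray(SIX_PEAK_AMPLITUDES, dtype=float)
    if amplitude_reweighting is not None:
        amps = np.asarray(
            amplitude_reweighting(SIX_PEAK_SHIFTS_PPM, tuple(amps), reference_te),
            dtype=float,
        )
    amps = amps / amps.sum()
    return FatSpectrum(
        shifts_ppm=SIX_PEAK_SHIFTS_PPM,
        amplitudes=tuple(amps),
        field_strength=field_strength,
    )


def water_fat_in_phase_period(spectrum: FatSpectrum) -> float:
    """Period (s) after which water and the dominant fat peak re-align.

    The dominant peak is the one with the largest amplitude; at 3 T with the
    methylene peak at -3.4 ppm this is about 2.3 ms.
    """
    dominant = int(np.argmax(spectrum.amplitudes))
    return 1.0 / abs(spectrum.frequencies_hz[dominant])
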