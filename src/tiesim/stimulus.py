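"""Two-tone interferential current stimulus.

Two sinusoidal currents I1(t) = A1 sin(2 pi f1 t + phi1) and
I2(t) = A2 sin(2 pi f2 t + phi2) are delivered through the two flanking
electrodes, with f1 = f_c (the carrier) and f2 = f_c + f_b (carrier plus
beat).  Amplitudes are per-electrode peak values in mA; the default
0.5 mA + 0.5 mA realises a total applied current of 1 mA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class StimulusSpec:
    """Amplitudes, frequencies and phases of the two-tone stimulus."""

    a1: float = 0.5  # mA, peak
    a2: float = 0.5  # mA, peak
    f1: float = 1000.0  # Hz
    f2: float = 1030.0  # Hz
    phi1: float = 0.0  # rad
    phi2: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("frequencies must be positive")

    @property
    def carrier(self) -> float:
        """Carrier frequency f_c = f1, Hz."""
        return self.f1

    @property
    def beat(self) -> float:
        """Beat frequency f_b = |f1 - f2|, Hz."""
        return abs(self.f1 - self.f2)

    @classmethod
    def from_frequencies(cls, fc: float, fb: float, **kwargs) -> "StimulusSpec":
        """Spec with f1 = f_c and f2 = f_c + f_b."""
        return cls(f1=fc, f2=fc + fb, **kwargs)


def ties_waveforms(spec: StimulusSpec, t) -> tuple[np.ndarray, np.ndarray]:
    """Electrode currents (I1, I2) in mA at times t (s)."""
    t = np.asarray(t, dtype=float)
    i1 = spec.a1 * np.sin(2.0 * np.pi * spec.f1 * t + spec.phi1)
    i2 = spec.a2 * np.sin(2.0 * np.pi * spec.f2 * t + spec.phi2)
    return i1, i2


def scaled(spec: StimulusSpec, k: float) -> StimulusSpec:
    """Stimulus with both amplitudes multiplied by the gain k > 0."""
    if k <= 0:
        raise ValueError("gain must be positive")
    return replace(spec, a1=spec.a1 * k, a2=spec.a2 * k)
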