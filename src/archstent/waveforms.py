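"""Pulsatile boundary-condition waveforms.

Both the inlet velocity and the outlet pressure are truncated Fourier series
with five cosine/sine harmonic pairs on the base angular frequency
omega = 14.77/2 rad/s (period ~0.851 s, ~70.5 bpm):

    w(t) = a0 + sum_{n=1..5} [ a_n cos(n omega t) + b_n sin(n omega t) ]

The default velocity series has mean 0.4248 m/s; the default oscillating
outlet-pressure series has mean 12564.24 Pa and swings between ~80 and
~120 mmHg over the cycle. A constant 100 mmHg outlet is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "OMEGA",
    "WaveformSpec",
    "inlet_velocity_spec",
    "pressure_outlet_spec",
]

MMHG_TO_PA = 133.322
#: Base angular frequency of the cardiac cycle [rad/s].
OMEGA = 14.77 / 2.0

_VEL_COS = (-0.06805, -0.08076, -0.04299, 0.01435, 0.01557)
_VEL_SIN = (0.1644, -0.00885, -0.0357, -0.02632, -0.005171)
_PRES_COS = (-749.36, -889.32, -473.40, 158.02, 171.46)
_PRES_SIN = (1810.36, -97.46, -393.13, -289.83, -56.94)


@dataclass(frozen=True)
class WaveformSpec:
    """Truncated Fourier series w(t) = const + sum a_n cos(n w t) + b_n sin(n w t)."""

    kind: Literal["velocity", "pressure"]
    constant: float
    cos_coeffs: Sequence[float] = field(default=())
    sin_coeffs: Sequence[float] = field(default=())
    omega: float = OMEGA

    def __post_init__(self) -> None:
        if len(self.cos_coeffs) != len(self.sin_coeffs):
            raise ValueError("cosine and sine coefficient lists must have equal length")
        if not self.omega > 0:
            raise ValueError("omega must be positive")

    @property
    def period(self) -> float:
        """Cycle period T = 2 pi / omega [s]."""
        return 2.0 * np.pi / self.omega

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.constant, dtype=float)
        for n, (a, b) in enumerate(zip(self.cos_coeffs, self.sin_coeffs), start=1):
            out = out + a * np.cos(n * self.omega * t) + b * np.sin(n * self.omega * t)
        return out if out.ndim else float(out)

    def extrema_times(self, n_samples: int = 4096) -> tuple[float, float]:
        """(t_peak, t_trough) within one period, by dense sampling + refinement."""
        t = np.linspace(0.0, self.period, n_samples, endpoint=False)
        v = self(t)
        return float(t[np.argmax(v)]), float(t[np.argmin(v)])


def eval_waveform(w: WaveformSpec, t):
    """Evaluate a waveform at time(s) t >= 0 [s]; periodic with w.period."""
    return w(t)


def inlet_velocity_spec() -> WaveformSpec:
    """Aortic-root inlet velocity waveform [m/s] replicating systole/diastole."""
    return WaveformSpec("velocity", 0.4248, _VEL_COS, _VEL_SIN)


def pressure_outlet_spec(mode: str = "constant") -> WaveformSpec:
    """Outlet pressure [Pa]: 'constant' (100 mmHg) or 'oscillating' (120/80 mmHg)."""
    if mode == "constant":
        return WaveformSpec("pressure", 100.0 * MMHG_TO_PA)
    if mode == "oscillating":
        return WaveformSpec("pressure", 12564.24, _PRES_COS, _PRES_SIN)
    raise ValueError(f"unknown outlet pressure mode {mode!r}")
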