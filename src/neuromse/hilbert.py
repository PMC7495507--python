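"""Hilbert spectral analysis of narrow-band components.

Each IMF is decomposed into an instantaneous amplitude (the modulus of
the analytic signal) and an instantaneous phase.  The phase enters
downstream complexity analysis through its cosine, which removes the
2*pi discontinuities of the wrapped phase while preserving its temporal
irregularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert as _scipy_hilbert

__all__ = ["BandComponents", "analytic_signal", "decompose_band"]


@dataclass
class BandComponents:
    """Spectral (IMF), amplitude-envelope and cosine-phase series of a band."""

    band: str
    spectral: np.ndarray
    amplitude: np.ndarray
    cos_phase: np.ndarray
    degenerate: bool = False

    def components(self) -> dict[str, np.ndarray]:
        return {"spectral": self.spectral,
                "amplitude": self.amplitude,
                "phase": self.cos_phase}


def analytic_signal(series: np.ndarray) -> np.ndarray:
    """Analytic signal: real part is the input, imaginary its Hilbert transform.

    Computed in the frequency domain by zeroing negative frequencies.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("series must be 1-D with length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    return _scipy_hilbert(x)


def decompose_band(imf: np.ndarray, band: str) -> BandComponents:
    """Split an IMF into envelope and cosine-phase via the analytic signal.

    A zero-valued IMF has no defined phase; the output is flagged
    degenerate and the cosine-phase set to zeros rather than masked.
    """
    x = np.asarray(imf, dtype=float)
    if not np.any(x):
        z = np.zeros_like(x)
        return BandComponents(band=band, spectral=x.copy(), amplitude=z,
                              cos_phase=z.copy(), degenerate=True)
    z = analytic_signal(x)
    amplitude = np.abs(z)
    cos_phase = np.cos(np.angle(z))
    return BandComponents(band=band, spectral=x, amplitude=amplitude,
                          cos_phase=cos_phase)
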