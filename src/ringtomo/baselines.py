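"""Wavelet–Fourier sinogram destriping (Münch-style comparator).

A multi-level 2-D wavelet decomposition isolates near-vertical structure
(detector lines, constant along the projection angle) in the vertical
detail bands; there a stripe occupies only the lowest angular
frequencies, so a high-pass Gaussian filter along the angle axis of each
band suppresses it. The sinogram is then rebuilt by the inverse wavelet
transform. This is a pre-processing comparator: it modifies the data
before reconstruction, unlike the joint solvers in
:mod:`ringtomo.solvers`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .geometry import Sinogram

__all__ = ["DestripeParams", "munch_destripe"]

_WAVELET_ALIASES = {
    "daubechies": "db",
    "symlet": "sym",
    "coiflet": "coif",
}


def _wavelet(name: str) -> pywt.Wavelet:
    """Accept both pywt codes ("db15") and spelled-out names ("Daubechies 15")."""
    key = name.strip().lower().replace("'", "")
    for long, short in _WAVELET_ALIASES.items():
        if key.startswith(long):
            key = short + key[len(long):].strip()
    return pywt.Wavelet(key.replace(" ", ""))


@dataclass
class DestripeParams:
    """levels — decomposition depth L; sigma — Gaussian damping bandwidth
    (in angular-frequency samples); wavelet_name — e.g. "db15" or
    "Daubechies 15"."""

    levels: int = 2
    sigma: float = 3.5
    wavelet_name: str = "db15"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def munch_destripe(sino: Sinogram, p: DestripeParams) -> Sinogram:
    """Suppress angle-constant detector lines by wavelet–Fourier filtering.

    At every decomposition level the vertical-detail band is Fourier
    transformed along the angle axis and multiplied by the high-pass gain
    g(k) = 1 − exp(−k²/(2σ²)); the DC component is damped by the same
    formula (g(0) = 0), which removes the angle-constant part of the band
    entirely. Output shape equals input shape.
    """
    values = sino.values
    if min(values.shape) < 2 ** p.levels:
        raise ValueError(
            f"decomposition depth {p.levels} too deep for shape {values.shape}"
        )
    wav = _wavelet(p.wavelet_name)
    coeffs = pywt.wavedec2(values, wav, mode="symmetric", level=p.levels)
    out = [coeffs[0]]
    for (cH, cV, cD) in coeffs[1:]:
        n_ang = cV.shape[0]
        k = np.fft.rfftfreq(n_ang, d=1.0 / n_ang)  # 0, 1, 2, ... cycles
        gain = 1.0 - np.exp(-(k ** 2) / (2.0 * p.sigma ** 2))
        spec = np.fft.rfft(cV, axis=0)
        cV_f = np.fft.irfft(spec * gain[:, None], n=n_ang, axis=0)
        out.append((cH, cV_f, cD))
    rebuilt = pywt.waverec2(out, wav, mode="symmetric")
    rebuilt = rebuilt[: values.shape[0], : values.shape[1]]
    return Sinogram(rebuilt, sino.geometry)
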