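"""FFT harmonic analysis of azimuthal curves and the square-wave coefficient.

A curve sampled uniformly over the full 0-360 deg window is decomposed as

    x(t) = a0 + sum_n An cos(n w0 t + phi_n),

where the harmonic index n counts cycles per 360 deg. The square-wave
coefficient

    Cs = |3 A3 - A1| + |5 A5 - A1| + |7 A7 - A1|

vanishes exactly when the odd-harmonic amplitudes satisfy the ideal
square-wave ratios A1 = 3 A3 = 5 A5 = 7 A7 (an ideal square wave of
amplitude A has An = 4A / (n pi) for odd n and 0 for even n). Cs is
therefore a scalar detector of square-wave-like period degeneracy.

Because the fundamental period of a degenerating four-periodic element is
half a turn (two cycles per 360 deg), the Cs helper accepts an explicit
index map designating which DFT bins play the roles of the 1st/3rd/5th/7th
harmonics; the default maps them to bins 2/6/10/14.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .ring import AzimuthalCurve

__all__ = [
    "HarmonicSpectrum",
    "harmonic_amplitudes",
    "square_wave_coefficient",
    "cs_from_spectrum",
    "classify_periodicity",
    "DEFAULT_CS_INDEX_MAP",
]

#: DFT bins (cycles per 360 deg) playing the 1st/3rd/5th/7th harmonic roles
#: for a degenerate four-periodic curve whose fundamental is a half turn.
DEFAULT_CS_INDEX_MAP: Mapping[int, int] = {1: 2, 3: 6, 5: 10, 7: 14}


@dataclass
class HarmonicSpectrum:
    """Baseline, per-harmonic amplitudes/phases of an azimuthal curve."""

    alpha0: float
    amplitudes: np.ndarray  # An for n = 1..n_max
    phases_deg: np.ndarray  # phi_n for n = 1..n_max
    n_samples: int
    cs: float | None = None  # set by cs_from_spectrum in batch analyses

    @property
    def n_max(self) -> int:
        return len(self.amplitudes)

    def amplitude(self, n: int) -> float:
        """An for harmonic index n (cycles per 360 deg); A0 is |alpha0|."""
        if n == 0:
            return abs(self.alpha0)
        if not 1 <= n <= self.n_max:
            raise ValueError(f"harmonic index {n} outside 1..{self.n_max}")
        return float(self.amplitudes[n - 1])

    def reconstruct(self, azimuths_deg: np.ndarray) -> np.ndarray:
        """Evaluate a0 + sum_n An cos(n w0 t + phi_n) at the given azimuths."""
        t = np.deg2rad(np.asarray(azimuths_deg, dtype=float))
        n = np.arange(1, self.n_max + 1)
        arg = np.outer(t, n) + np.deg2rad(self.phases_deg)[None, :]
        return self.alpha0 + np.cos(arg) @ self.amplitudes

    def dominant_harmonic(self) -> int:
        """Index n >= 1 with the largest amplitude."""
        return int(np.argmax(self.amplitudes)) + 1

    def ac_energy(self) -> float:
        """Mean-square AC power sum(An^2)/2 (Parseval surrogate)."""
        return float(np.sum(self.amplitudes**2) / 2.0)


def harmonic_amplitudes(curve, n_max: int | None = None) -> HarmonicSpectrum:
    """Discrete Fourier spectrum of a uniformly sampled azimuthal curve.

    Amplitudes use the 2/N normalization, so a unit-amplitude cosine of any
    harmonic yields An = 1. Accepts an :class:`~mmoblique.ring.AzimuthalCurve`
    or a plain value array (assumed uniform over [0, 360)).
    """
    if isinstance(curve, AzimuthalCurve):
        if not curve.is_uniform():
            raise ValueError("harmonic analysis requires a uniform azimuth grid")
        values = curve.values
    else:
        values = np.asarray(curve, dtype=float)
    n = len(values)
    if not np.all(np.isfinite(values)):
        raise ValueError("harmonic analysis requires finite (unmasked) values")
    limit = (n - 1) // 2  # exclude the Nyquist bin from the 2/N convention
    if n_max is None:
        n_max = limit
    if not 1 <= n_max <= limit:
        raise ValueError(f"n_max must be in 1..{limit} for {n} samples")
    spectrum = np.fft.rfft(values)
    amplitudes = 2.0 * np.abs(spectrum[1 : n_max + 1]) / n
    phases = np.degrees(np.angle(spectrum[1 : n_max + 1]))
    return HarmonicSpectrum(
        alpha0=float(spectrum[0].real / n),
        amplitudes=amplitudes,
        phases_deg=phases,
        n_samples=n,
    )


def square_wave_coefficient(a1: float, a3: float, a5: float, a7: float) -> float:
    """Cs = |3 A3 - A1| + |5 A5 - A1| + |7 A7 - A1|.

    Zero iff the amplitudes satisfy the ideal square-wave ratios
    A1 = 3 A3 = 5 A5 = 7 A7.
    """
    for name, a in (("a1", a1), ("a3", a3), ("a5", a5), ("a7", a7)):
        if a < 0:
            raise ValueError(f"harmonic amplitude {name} must be >= 0; got {a}")
    return abs(3.0 * a3 - a1) + abs(5.0 * a5 - a1) + abs(7.0 * a7 - a1)


def cs_from_spectrum(
    spectrum: HarmonicSpectrum,
    index_map: Mapping[int, int] = DEFAULT_CS_INDEX_MAP,
) -> float:
    """Cs of a spectrum, with an explicit odd-harmonic-role index map.

    ``index_map`` maps the roles {1, 3, 5, 7} to DFT bin indices; the
    default treats a half-turn (2 cycles per 360 deg) as the fundamental,
    appropriate for degenerating four-periodic elements.
    """
    missing = {1, 3, 5, 7} - set(index_map)
    if missing:
        raise ValueError(f"index_map must provide roles 1, 3, 5, 7; missing {missing}")
    a = {role: spectrum.amplitude(index_map[role]) for role in (1, 3, 5, 7)}
    return square_wave_coefficient(a[1], a[3], a[5], a[7])


def classify_periodicity(
    spectrum: HarmonicSpectrum,
    expected: str | None = None,
    amplitude_floor: float = 0.02,
    dominance_fraction: float = 0.3,
) -> str:
    """Label a spectrum as non-periodic / two-periodic / four-periodic / degenerate.

    A curve is non-periodic when no harmonic rises above
    ``amplitude_floor`` or the dominant harmonic carries less than
    ``dominance_fraction`` of the baseline-removed energy. Otherwise the
    label follows the dominant harmonic index (2 or 4); any other dominant
    index — or, when ``expected`` is given, a dominant index disagreeing
    with the expected undistorted class — is reported as "degenerate".
    """
    if spectrum.n_max < 8:
        raise ValueError("classification requires a spectrum with n_max >= 8")
    energy = spectrum.ac_energy()
    peak = float(np.max(spectrum.amplitudes))
    if peak < amplitude_floor or (
        energy > 0 and (peak**2 / 2.0) / energy < dominance_fraction
    ):
        return "non-periodic"
    dominant = spectrum.dominant_harmonic()
    label = {2: "two-periodic", 4: "four-periodic"}.get(dominant, "degenerate")
    if expected is not None and label != expected:
        return "degenerate"
    return label
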