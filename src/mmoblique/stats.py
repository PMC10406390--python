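"""Descriptive statistics of azimuthal curves and element images.

Implements the study's quantitative evaluation surfaces: curve mean and
(non-excess, population) kurtosis, circular peak/valley metrics including
the twin-peak gap that tracks period degeneracy, and frequency
distribution histograms (FDHs) of element images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .image import ElementIndex, MMImage, check_element_index
from .ring import AzimuthalCurve

__all__ = [
    "CurveStats",
    "PeakSet",
    "FDH",
    "curve_mean",
    "curve_kurtosis",
    "curve_stats",
    "find_peaks_valleys",
    "compute_fdh",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurveStats:
    mean: float
    kurtosis: float


def _finite_values(values) -> np.ndarray:
    if isinstance(values, AzimuthalCurve):
        values = values.values
    values = np.asarray(values, dtype=float).ravel()
    return values[np.isfinite(values)]


def curve_mean(values) -> float:
    """Arithmetic mean of the unmasked curve values."""
    v = _finite_values(values)
    if v.size == 0:
        raise ValueError("cannot compute the mean of an empty (or fully masked) curve")
    return float(np.mean(v))


def curve_kurtosis(values) -> float:
    """Population (biased, non-excess) kurtosis: m4 / m2^2.

    A normal sample gives ~3; dense samples of a sinusoid give 1.5; any
    non-constant finite sample gives >= 1. Invariant under affine
    transforms a*p + b (a != 0). Raises on zero-variance input rather than
    returning NaN.
    """
    v = _finite_values(values)
    if v.size < 2:
        raise ValueError("kurtosis requires at least two finite values")
    mu = np.mean(v)
    m2 = np.mean((v - mu) ** 2)
    if m2 == 0.0:
        raise ValueError(
            "kurtosis is undefined for a constant (zero-variance) curve"
        )
    m4 = np.mean((v - mu) ** 4)
    return float(m4 / m2**2)


def curve_stats(values) -> CurveStats:
    return CurveStats(mean=curve_mean(values), kurtosis=curve_kurtosis(values))


@dataclass
class PeakSet:
    """Circular peak/valley structure of one azimuthal curve.

    ``pp_values`` are absolute differences between the heights of
    consecutive peaks lying in the same half-turn (0-180 or 180-360 deg)
    window; ``pv_values`` are absolute peak-to-following-valley
    differences; ``pp_gap`` is the mean azimuthal distance between twin
    peaks (the smaller half of the circular peak separations, accepted when
    below one nominal period), expressed in normalized period units — a
    full two-period span, 2 x nominal_period, is 1.0. NaN when the peaks
    show no twin structure.
    """

    peak_azimuths_deg: np.ndarray
    peak_values: np.ndarray
    valley_azimuths_deg: np.ndarray
    valley_values: np.ndarray
    pp_values: np.ndarray
    pv_values: np.ndarray
    pp_gap: float
    nominal_period_deg: float = 90.0

    @property
    def n_peaks(self) -> int:
        return len(self.peak_azimuths_deg)

    @property
    def n_valleys(self) -> int:
        return len(self.valley_azimuths_deg)


def _circular_smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    padded = np.concatenate([values[-window:], values, values[:window]])
    sm = np.convolve(padded, kernel, mode="same")
    return sm[window:-window]


def _circular_extrema(
    values: np.ndarray, prominence: float
) -> np.ndarray:
    """Indices of local maxima with circular boundary handling."""
    n = len(values)
    tiled = np.concatenate([values, values, values])
    idx, _ = _scipy_find_peaks(tiled, prominence=prominence)
    idx = idx[(idx >= n) & (idx < 2 * n)] - n
    return np.sort(idx)


def _refine(az: np.ndarray, sm: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample extremum azimuths by parabolic interpolation."""
    n = len(sm)
    step = az[1] - az[0] if len(az) > 1 else 1.0
    out = np.empty(len(idx))
    for k, i in enumerate(idx):
        y0, y1, y2 = sm[(i - 1) % n], sm[i], sm[(i + 1) % n]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        out[k] = (az[i] + delta * step) % 360.0
    return out


def find_peaks_valleys(
    curve: AzimuthalCurve,
    prominence_fraction: float = 0.05,
    smooth_window: int = 5,
    nominal_period_deg: float = 90.0,
) -> PeakSet:
    """Detect peaks and valleys of a circular azimuthal curve.

    The curve is lightly smoothed (circular moving average) before
    extremum detection; detected locations are refined by parabolic
    interpolation and the reported heights are the raw curve values at the
    nearest grid sample. Extrema must have prominence of at least
    ``prominence_fraction`` times the curve range.
    """
    if curve.n_samples < 8:
        raise ValueError("peak detection requires at least 8 curve samples")
    raw = curve.values
    finite = np.isfinite(raw)
    if not np.all(finite):
        # interpolate over masked samples for detection only
        raw = np.interp(
            curve.azimuths_deg,
            curve.azimuths_deg[finite],
            raw[finite],
            period=360.0,
        )
    sm = _circular_smooth(raw, smooth_window)
    vrange = float(np.max(sm) - np.min(sm))
    prominence = prominence_fraction * vrange if vrange > 0 else np.inf
    peak_idx = _circular_extrema(sm, prominence)
    valley_idx = _circular_extrema(-sm, prominence)

    if len(peak_idx) == 0 and len(valley_idx) == 0:
        warnings.warn(
            "no extrema above the prominence threshold; returning an empty PeakSet",
            stacklevel=2,
        )
        empty = np.array([])
        return PeakSet(empty, empty, empty, empty, empty, empty, np.nan,
                       nominal_period_deg)

    peak_az = _refine(curve.azimuths_deg, sm, peak_idx)
    valley_az = _refine(curve.azimuths_deg, -sm, valley_idx)
    peak_val = curve.values[peak_idx]
    valley_val = curve.values[valley_idx]
    order = np.argsort(peak_az)
    peak_az, peak_val = peak_az[order], peak_val[order]
    order = np.argsort(valley_az)
    valley_az, valley_val = valley_az[order], valley_val[order]

    # P-P: consecutive peak-height differences within each half-turn window
    pp = [
        abs(peak_val[k + 1] - peak_val[k])
        for k in range(len(peak_az) - 1)
        if int(peak_az[k] // 180.0) == int(peak_az[k + 1] // 180.0)
    ]

    # P-V: each peak against the next valley in circular azimuth order
    pv = []
    if len(valley_az) > 0:
        for az_p, v_p in zip(peak_az, peak_val):
            ahead = np.where(valley_az > az_p)[0]
            j = ahead[0] if len(ahead) else 0  # wrap
            pv.append(abs(v_p - valley_val[j]))

    # twin-peak gap: in a twin-peak structure the circular peak separations
    # alternate between the (smaller) intra-pair gap and the (larger)
    # pair-to-pair spacing; the smaller half of the separations is the twin
    # gap. Robust to global phase shifts of the curve, unlike fixed windows.
    pp_gap = float("nan")
    if len(peak_az) >= 2:
        seps = np.diff(np.concatenate([peak_az, [peak_az[0] + 360.0]]))
        smaller = np.sort(seps)[: len(seps) // 2]
        if len(smaller) and np.mean(smaller) < nominal_period_deg:
            pp_gap = float(np.mean(smaller)) / (2.0 * nominal_period_deg)

    return PeakSet(
        peak_azimuths_deg=peak_az,
        peak_values=peak_val,
        valley_azimuths_deg=valley_az,
        valley_values=valley_val,
        pp_values=np.asarray(pp, dtype=float),
        pv_values=np.asarray(pv, dtype=float),
        pp_gap=pp_gap,
        nominal_period_deg=nominal_period_deg,
    )


@dataclass
class FDH:
    """Frequency distribution histogram of an element image region."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def centroid(self) -> float:
        total = self.counts.sum()
        if total == 0:
            return float("nan")
        return float(np.sum(self.bin_centers * self.counts) / total)


def compute_fdh(
    mm: MMImage,
    element_index: ElementIndex,
    roi_mask: np.ndarray | None = None,
    n_bins: int = 256,
    value_range: Tuple[float, float] = (-1.0, 1.0),
) -> FDH:
    """Histogram of the unmasked ROI pixels of one element image.

    Values outside ``value_range`` are clipped into the boundary bins so
    that the counts always conserve the number of unmasked ROI pixels.
    """
    element_index = check_element_index(element_index)
    img = mm.channel(element_index)
    if roi_mask is None:
        roi_mask = np.ones(img.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != img.shape:
        raise ValueError("roi_mask shape must match the image")
    vals = img[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty ROI: no unmasked pixels to histogram")
    lo, hi = value_range
    vals = np.clip(vals, lo, hi)
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return FDH(bin_edges=edges, counts=counts, n_pixels=int(vals.size))
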