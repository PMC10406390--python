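"""Synthetic concentric-fiber phantom with oblique-incidence distortions.

The generator emulates the backscattering Mueller-matrix image of an
anisotropic phantom made of concentrically aligned fibers. Under normal
incidence the azimuthal dependence of the (M11-normalized) elements falls
into three families:

* diagonal elements M11, M44 — azimuth-independent (non-periodic);
* off-diagonal elements M12, M21, M13, M31 — two oscillation periods per
  360 deg (linear diattenuation / polarizance block);
* central-block elements M22, M33, M23, M32 — four periods per 360 deg
  (linear depolarization / anisotropy block).

Oblique incidence at angle ``theta`` (between the illumination and
detection arms) distorts these curves. The distortion knobs — baseline
shift, symmetry breaking between transpose pairs, period-degeneracy
collapse, phase retardance, element transposition, and an azimuthal
modulation of the diagonal elements — are each smooth monotone functions
of ``theta``; their exact functional forms are this package's own
phenomenological model (the physical effects they emulate are produced by
the tilted acquisition geometry, not modeled from first principles here).

The period-degeneracy collapse deserves a note: collapse depth ``c`` in
[0, 1] blends the four-periodic cosine toward an element-specific
degenerate waveform with two periods per 360 deg. For the square-wave
mode (M33) the target is the power-law-compressed cosine
``sign(u) |u|^(1-c)`` with ``u = cos(2(phi - 45 deg))``, which at c = 1 is
an ideal square wave with transitions at +-45 deg and whose twin peaks
(riding on the fading four-periodic ripple) converge monotonically toward
45 deg / 135 deg as ``c`` grows. For the impulse mode (M22) the target is
the sharpening impulse train ``|sin(phi)|^(2m)`` peaked at 90 deg /
270 deg, so the original peaks at 0 deg / 180 deg collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Tuple

import numpy as np

from .image import ALL_ELEMENTS, ElementIndex, MMImage, check_element_index, element_name

__all__ = [
    "CurveCoefficients",
    "DistortionState",
    "DistortionProfile",
    "PhantomParams",
    "element_group",
    "azimuthal_element_model",
    "generate_phantom_mm",
    "ground_truth_curves",
    "DIAGONAL_ELEMENTS",
    "TWO_PERIODIC_ELEMENTS",
    "FOUR_PERIODIC_ELEMENTS",
]

DIAGONAL_ELEMENTS = {(1, 1), (4, 4)}
TWO_PERIODIC_ELEMENTS = {(1, 2), (2, 1), (1, 3), (3, 1)}
FOUR_PERIODIC_ELEMENTS = {(2, 2), (3, 3), (2, 3), (3, 2)}
WEAK_ELEMENTS = {(1, 4), (4, 1), (2, 4), (4, 2), (3, 4), (4, 3)}

#: transpose pairs affected by symmetry breaking and transposition
TRANSPOSE_PAIRS: Dict[ElementIndex, ElementIndex] = {
    (1, 2): (2, 1),
    (2, 1): (1, 2),
    (1, 3): (3, 1),
    (3, 1): (1, 3),
}

#: period-degeneracy mode of each four-periodic element
COLLAPSE_MODES: Dict[ElementIndex, str] = {
    (2, 2): "impulse",
    (3, 3): "square",
    (2, 3): "generic",
    (3, 2): "generic",
}

#: elements whose amplitude grows (+) or shrinks (-) under symmetry breaking
_SYMMETRY_SIGN = {(1, 2): +1.0, (1, 3): +1.0, (2, 1): -1.0, (3, 1): -1.0}


def element_group(index: ElementIndex) -> str:
    """Periodicity family of an element: diagonal / two / four / weak."""
    index = check_element_index(index)
    if index in DIAGONAL_ELEMENTS:
        return "diagonal"
    if index in TWO_PERIODIC_ELEMENTS:
        return "two-periodic"
    if index in FOUR_PERIODIC_ELEMENTS:
        return "four-periodic"
    return "weak"


@dataclass(frozen=True)
class CurveCoefficients:
    """Undistorted trigonometric curve of one element: B + A cos(p(phi - phase))."""

    amplitude: float
    baseline: float
    phase_deg: float = 0.0


# Default curve coefficients. The source study plots the phantom curves but
# never tabulates their amplitudes or baselines, so these are documented
# package choices giving physically bounded (|m| <= 1) normalized elements
# with clearly resolved periodic structure; see docs/methods.md.
DEFAULT_COEFFICIENTS: Dict[ElementIndex, CurveCoefficients] = {
    (1, 1): CurveCoefficients(0.0, 1.0),
    (4, 4): CurveCoefficients(0.0, 0.55),
    (1, 2): CurveCoefficients(0.25, 0.0, 0.0),
    (2, 1): CurveCoefficients(0.25, 0.0, 0.0),
    (1, 3): CurveCoefficients(0.25, 0.0, 45.0),
    (3, 1): CurveCoefficients(0.25, 0.0, 45.0),
    (2, 2): CurveCoefficients(0.30, 0.30, 0.0),
    (3, 3): CurveCoefficients(0.30, 0.30, 0.0),
    (2, 3): CurveCoefficients(0.30, 0.0, 22.5),
    (3, 2): CurveCoefficients(0.30, 0.0, 22.5),
    (1, 4): CurveCoefficients(0.0, 0.02),
    (4, 1): CurveCoefficients(0.0, 0.02),
    (2, 4): CurveCoefficients(0.0, 0.02),
    (4, 2): CurveCoefficients(0.0, 0.02),
    (3, 4): CurveCoefficients(0.0, 0.02),
    (4, 3): CurveCoefficients(0.0, 0.02),
}


@dataclass(frozen=True)
class DistortionState:
    """Scalar distortion values in effect at one incidence angle.

    All values are dimensionless except ``phase_retardance_deg``.
    ``transposition`` is a mixing weight in [0, 1] between an off-diagonal
    element and its transpose partner.
    """

    baseline_shift: float = 0.0
    symmetry_breaking: float = 0.0
    collapse_depth: float = 0.0
    phase_retardance_deg: float = 0.0
    transposition: float = 0.0
    diagonal_modulation: float = 0.0

    def is_zero(self) -> bool:
        return all(
            v == 0.0
            for v in (
                self.baseline_shift,
                self.symmetry_breaking,
                self.collapse_depth,
                self.phase_retardance_deg,
                self.transposition,
                self.diagonal_modulation,
            )
        )


@dataclass(frozen=True)
class DistortionProfile:
    """Maps incidence angle theta (deg) to a :class:`DistortionState`.

    Smooth knobs scale with sin(theta) (zero at normal incidence, saturating
    toward grazing); element transposition switches on through a logistic
    gate above ``transposition_threshold_deg``, emulating the qualitatively
    different regime seen beyond prominent oblique incidence.
    """

    baseline_shift_max: float = 0.15
    symmetry_breaking_max: float = 0.6
    # capped at 1; reaches ~0.80 at 50 deg so the residual four-periodic
    # ripple (the twin peaks) stays above the default peak-prominence floor
    # across the 5-50 deg sweep
    collapse_depth_max: float = 1.05
    phase_retardance_max_deg: float = 20.0
    diagonal_modulation_max: float = 0.15
    transposition_threshold_deg: float = 60.0
    transposition_width_deg: float = 2.5

    def at(self, theta_deg: float) -> DistortionState:
        s = math.sin(math.radians(theta_deg))
        gate = 1.0 / (
            1.0
            + math.exp(
                -(theta_deg - self.transposition_threshold_deg)
                / self.transposition_width_deg
            )
        )
        return DistortionState(
            baseline_shift=self.baseline_shift_max * s,
            symmetry_breaking=min(1.0, self.symmetry_breaking_max * s),
            collapse_depth=min(1.0, self.collapse_depth_max * s),
            phase_retardance_deg=self.phase_retardance_max_deg * s,
            transposition=gate,
            diagonal_modulation=self.diagonal_modulation_max * s,
        )


@dataclass(frozen=True)
class PhantomParams:
    """Complete description of one synthetic phantom acquisition."""

    image_size: Tuple[int, int] = (460, 460)
    center: Tuple[float, float] | None = None  # (row, col); default image center
    ring_radius: float = 200.0
    # painted annulus is wider than the 5 px analysis ring so that ring
    # sampling never interpolates across the fiber/background boundary
    ring_half_width: float = 12.0
    incidence_theta: float = 0.0
    coefficients: Mapping[ElementIndex, CurveCoefficients] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    profile: DistortionProfile = field(default_factory=DistortionProfile)
    distortion: DistortionState | None = None  # overrides profile.at(theta) if set
    noise_sigma: float = 0.0
    seed: int = 0

    @property
    def center_rc(self) -> Tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.image_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    def distortion_state(self) -> DistortionState:
        if self.distortion is not None:
            return self.distortion
        return self.profile.at(self.incidence_theta)

    def validate(self) -> None:
        h, w = self.image_size
        if self.ring_radius <= 0:
            raise ValueError(f"degenerate ring geometry: radius {self.ring_radius} <= 0")
        if self.ring_half_width < 0:
            raise ValueError("ring_half_width must be non-negative")
        cy, cx = self.center_rc
        margin = min(cy, cx, h - 1 - cy, w - 1 - cx)
        if self.ring_radius + self.ring_half_width > margin:
            raise ValueError(
                "degenerate ring geometry: annulus (radius "
                f"{self.ring_radius} + half width {self.ring_half_width}) exceeds "
                f"the distance {margin:.1f} px from center to the nearest image edge"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = {
            element_name(k): asdict(v) for k, v in self.coefficients.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomParams":
        d = dict(d)
        if "coefficients" in d and d["coefficients"] is not None:
            coeffs = {}
            for name, cd in d["coefficients"].items():
                idx = (int(name[1]), int(name[2]))
                coeffs[idx] = CurveCoefficients(**cd)
            d["coefficients"] = coeffs
        if d.get("profile") is not None and not isinstance(d["profile"], DistortionProfile):
            d["profile"] = DistortionProfile(**d["profile"])
        if d.get("distortion") is not None and not isinstance(d["distortion"], DistortionState):
            d["distortion"] = DistortionState(**d["distortion"])
        if d.get("image_size") is not None:
            d["image_size"] = tuple(d["image_size"])
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        return cls(**d)


def _sin_power_mean(m: float) -> float:
    """Mean of |sin(phi)|^(2m) over a full period (Wallis integral)."""
    return math.gamma(m + 0.5) / (math.sqrt(math.pi) * math.gamma(m + 1.0))


def _collapse_shape(mode: str, x_deg: np.ndarray, c: float) -> np.ndarray:
    """Unit-amplitude four-periodic shape under collapse depth ``c`` in [0, 1].

    ``x_deg`` is azimuth relative to the element phase. At c = 0 this is
    exactly cos(4x); as c grows the curve blends toward the degenerate
    two-period waveform of the given mode.
    """
    x = np.deg2rad(x_deg)
    four = np.cos(4.0 * x)
    if c <= 0.0:
        return four
    c = min(float(c), 1.0)
    bw = min(c / 0.05, 1.0)  # degenerate component switches in quickly
    if mode == "square":
        u = np.cos(2.0 * (x - np.pi / 4.0))
        a = 1.0 - c
        target = np.sign(u) * np.abs(u) ** a if a > 0 else np.sign(u)
    elif mode == "impulse":
        m = 1.0 + 5.0 * c
        j = np.abs(np.sin(x)) ** (2.0 * m)
        mu = _sin_power_mean(m)
        target = (j - mu) / (1.0 - mu)
    elif mode == "generic":
        target = np.cos(2.0 * x)
    else:  # pragma: no cover - internal consistency
        raise ValueError(f"unknown collapse mode {mode!r}")
    return (1.0 - c) * four + bw * target


def _raw_element_curve(
    index: ElementIndex, azimuth_deg: np.ndarray, params: PhantomParams
) -> np.ndarray:
    """Element curve before transposition mixing."""
    coeff = params.coefficients.get(index, DEFAULT_COEFFICIENTS[index])
    d = params.distortion_state()
    group = element_group(index)
    az = np.asarray(azimuth_deg, dtype=float)

    if group == "diagonal":
        if index == (1, 1):
            # normalizer: identically 1 in the normalized image
            return np.ones_like(az)
        base = coeff.baseline - d.baseline_shift
        mod = d.diagonal_modulation * np.cos(2.0 * np.deg2rad(az - 90.0))
        return base + mod * np.ones_like(az)

    if group == "weak":
        return np.full_like(az, coeff.baseline)

    x = az - coeff.phase_deg - d.phase_retardance_deg

    if group == "two-periodic":
        sign = _SYMMETRY_SIGN[index]
        amp = coeff.amplitude * (1.0 + sign * d.symmetry_breaking)
        base = coeff.baseline + sign * d.baseline_shift
        return base + amp * np.cos(2.0 * np.deg2rad(x))

    # four-periodic
    shape = _collapse_shape(COLLAPSE_MODES[index], x, d.collapse_depth)
    return (coeff.baseline - d.baseline_shift) + coeff.amplitude * shape


def azimuthal_element_model(
    index: ElementIndex, azimuth_deg, params: PhantomParams
) -> np.ndarray:
    """Ground-truth value of one normalized element at the given azimuth(s).

    Azimuth is measured counterclockwise from the +x image axis, in degrees
    over [0, 360). Deterministic (noise-free); noise is only added during
    rasterization by :func:`generate_phantom_mm`.
    """
    index = check_element_index(index)
    az = np.asarray(azimuth_deg, dtype=float)
    value = _raw_element_curve(index, az, params)
    partner = TRANSPOSE_PAIRS.get(index)
    if partner is not None:
        g = params.distortion_state().transposition
        if g > 0.0:
            value = (1.0 - g) * value + g * _raw_element_curve(partner, az, params)
    if np.isscalar(azimuth_deg):
        return float(value)
    return value


def generate_phantom_mm(params: PhantomParams, normalized: bool = True) -> MMImage:
    """Rasterize the phantom model into a 16-channel Mueller-matrix image.

    Every pixel inside the ring annulus takes the value of
    :func:`azimuthal_element_model` at that pixel's azimuth; background
    pixels take 0, except the M11 channel whose background is 1. Zero-mean
    Gaussian noise of width ``params.noise_sigma`` (seeded by
    ``params.seed``) is added to every channel. With ``normalized=False``
    the channels are multiplied pixelwise by an M11 intensity pattern
    carrying the diagonal azimuthal modulation, emulating the raw
    (unnormalized) measurement.
    """
    params.validate()
    h, w = params.image_size
    cy, cx = params.center_rc
    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - cy
    dx = cols - cx
    radius = np.hypot(dy, dx)
    azimuth = np.degrees(np.arctan2(dy, dx)) % 360.0
    annulus = np.abs(radius - params.ring_radius) <= params.ring_half_width

    elements = np.zeros((4, 4, h, w))
    elements[0, 0] = 1.0  # M11 background
    az_in = azimuth[annulus]
    for index in ALL_ELEMENTS:
        i, j = index
        elements[i - 1, j - 1][annulus] = azimuthal_element_model(index, az_in, params)

    if not normalized:
        d = params.distortion_state()
        m11_pattern = np.ones((h, w))
        m11_pattern[annulus] = 1.0 + d.diagonal_modulation * np.cos(
            2.0 * np.deg2rad(az_in - 90.0)
        )
        elements = elements * m11_pattern[None, None, :, :]

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        elements = elements + rng.normal(0.0, params.noise_sigma, size=elements.shape)

    return MMImage(
        elements=elements,
        normalized=normalized,
        incidence_theta=params.incidence_theta,
        provenance="phantom",
        metadata={"params": params.to_dict()},
    )


def ground_truth_curves(params: PhantomParams, n_samples: int = 360) -> "np.ndarray":
    """All 16 ground-truth curves on a uniform azimuth grid.

    Returns a structured result as a dict-like pandas-free pair:
    ``(azimuths_deg, {element_name: values})``.
    """
    az = np.arange(n_samples) * (360.0 / n_samples)
    curves = {
        element_name(index): azimuthal_element_model(index, az, params)
        for index in ALL_ELEMENTS
    }
    return az, curves
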