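"""Azimuthal curve extraction along an annular ring of an element image.

For each azimuth sample the element value is averaged over the radial
extent [radius - half_width, radius + half_width] using bilinear
interpolation of the pixel grid; masked (NaN) pixels are excluded from the
average. Azimuth 0 lies along the +x image axis and increases
counterclockwise, matching the phantom generator's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .image import ALL_ELEMENTS, ElementIndex, MMImage, check_element_index, element_name

__all__ = ["AzimuthalCurve", "extract_azimuthal_curve", "extract_all_curves"]


@dataclass
class AzimuthalCurve:
    """One element's value versus ring azimuth over [0, 360)."""

    element_index: ElementIndex
    azimuths_deg: np.ndarray  # strictly increasing uniform grid
    values: np.ndarray  # NaN where the azimuth ray was fully masked
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.azimuths_deg = np.asarray(self.azimuths_deg, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.azimuths_deg) != len(self.values):
            raise ValueError("azimuth and value arrays must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def step_deg(self) -> float:
        return 360.0 / self.n_samples

    def is_uniform(self, tol: float = 1e-9) -> bool:
        d = np.diff(self.azimuths_deg)
        return bool(np.all(np.abs(d - d[0]) < tol))


def extract_azimuthal_curve(
    mm: MMImage,
    element_index: ElementIndex,
    center: Tuple[float, float] | None = None,
    radius: float = 200.0,
    half_width: float = 5.0,
    n_samples: int = 360,
    n_radial: int = 11,
) -> AzimuthalCurve:
    """Sample one element along a ring and average across its radial extent.

    ``center`` is (row, col); by default the image center. ``n_radial``
    sub-samples span the radial extent of the ring at each azimuth.
    """
    element_index = check_element_index(element_index)
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    img = mm.channel(element_index)
    h, w = img.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cy, cx = center
    margin = min(cy, cx, h - 1 - cy, w - 1 - cx)
    if radius + half_width > margin or radius - half_width < 0:
        raise ValueError(
            f"ring (radius {radius} +- {half_width}) extends outside the image: "
            f"the center is only {margin:.1f} px from the nearest edge"
        )

    azimuths = np.arange(n_samples) * (360.0 / n_samples)
    az_rad = np.deg2rad(azimuths)
    if n_radial > 1 and half_width > 0:
        radii = np.linspace(radius - half_width, radius + half_width, n_radial)
    else:
        radii = np.array([radius])
    rr, aa = np.meshgrid(radii, az_rad, indexing="ij")
    rows = cy + rr * np.sin(aa)
    cols = cx + rr * np.cos(aa)
    sampled = ndimage.map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=1, mode="nearest", cval=np.nan
    ).reshape(rr.shape)
    # NaNs in the input propagate through bilinear weights; average the
    # unmasked radial sub-samples per azimuth (NaN where all are masked).
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(sampled, axis=0)
    return AzimuthalCurve(
        element_index=element_index,
        azimuths_deg=azimuths,
        values=values,
        provenance={
            "center": (float(cy), float(cx)),
            "radius": float(radius),
            "half_width": float(half_width),
            "n_radial": int(n_radial),
            "source": mm.provenance,
        },
    )


def extract_all_curves(
    mm: MMImage, **kwargs
) -> Dict[str, AzimuthalCurve]:
    """Extract the curves of all 16 elements; keys are 'm11'..'m44'."""
    return {
        element_name(index): extract_azimuthal_curve(mm, index, **kwargs)
        for index in ALL_ELEMENTS
    }
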