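"""Dual-rotating-retarder (DRR) acquisition: forward rendering and inversion.

The polarimeter records ``n_frames`` intensity images while two
quarter-wave plates rotate at a fixed 1:5 rate ratio — R1 in the
polarization state generator (fixed horizontal polarizer P1 followed by
R1) and R2 in the analyzer (R2 followed by fixed horizontal polarizer
P2). Each frame's intensity at a pixel is a known linear functional of
the 16 Mueller elements at that pixel, so the per-pixel Mueller matrix is
recovered by solving the stacked linear system with a pseudoinverse.

The classical route decodes the elements from the Fourier coefficients of
the intensity signal (I = a0 + sum over n of an cos(n w t) + bn sin(n w t),
n up to 12); that truncated-series fit is provided as a diagnostic surface,
while reconstruction itself uses the numerically equivalent and more robust
least-squares inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .image import MMImage
from .mueller import linear_polarizer, linear_retarder, unpolarized_stokes

__all__ = [
    "AcquisitionConfig",
    "FrameSet",
    "FourierCoefficients",
    "measurement_row",
    "design_matrix",
    "render_frames",
    "fit_fourier_coefficients",
    "reconstruct_mm",
    "normalize_by_m11",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry and timing of one DRR acquisition.

    ``r1_step_deg`` is the generator retarder increment per frame; the
    analyzer retarder steps at ``rate_ratio`` times that (1:5 in the
    standard scheme). ``retardance_deg = 90`` corresponds to ideal
    quarter-wave plates. Both polarizers are fixed at
    ``polarizer_angle_deg`` (horizontal by default).
    """

    n_frames: int = 30
    r1_step_deg: float = 6.0
    rate_ratio: float = 5.0
    retardance_deg: float = 90.0
    polarizer_angle_deg: float = 0.0
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 16:
            raise ValueError(f"n_frames must be >= 16; got {self.n_frames}")

    @property
    def r1_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.r1_step_deg

    @property
    def r2_angles_deg(self) -> np.ndarray:
        return self.r1_angles_deg * self.rate_ratio


@dataclass
class FrameSet:
    """The raw intensity frames of one acquisition plus retarder angles."""

    frames: np.ndarray  # (n_frames, H, W)
    r1_angles_deg: np.ndarray
    r2_angles_deg: np.ndarray
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.r1_angles_deg = np.asarray(self.r1_angles_deg, dtype=float)
        self.r2_angles_deg = np.asarray(self.r2_angles_deg, dtype=float)
        n = self.frames.shape[0]
        if not (len(self.r1_angles_deg) == len(self.r2_angles_deg) == n):
            raise ValueError("angle arrays must match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def measurement_row(
    r1_angle_deg: float, r2_angle_deg: float, config: AcquisitionConfig
) -> np.ndarray:
    """Weights w such that intensity = w . vec(M) (row-major vec).

    Built from Mueller calculus: the generator Stokes vector is
    R1(delta, r1) P1 S_unpolarized and the analyzer row is the first row
    of P2 R2(delta, r2); the intensity for sample matrix M is
    a^T M s = sum_ij a_i M_ij s_j.
    """
    pol = linear_polarizer(config.polarizer_angle_deg)
    generator = linear_retarder(config.retardance_deg, r1_angle_deg) @ pol
    analyzer = pol @ linear_retarder(config.retardance_deg, r2_angle_deg)
    s = generator @ unpolarized_stokes(1.0)
    a = analyzer[0, :]
    return np.outer(a, s).ravel()


def design_matrix(config: AcquisitionConfig) -> np.ndarray:
    """The (n_frames, 16) polarimetric measurement matrix of a config."""
    return np.stack(
        [
            measurement_row(r1, r2, config)
            for r1, r2 in zip(config.r1_angles_deg, config.r2_angles_deg)
        ]
    )


def render_frames(mm: MMImage, config: AcquisitionConfig) -> FrameSet:
    """Forward-render the DRR intensity frames of a Mueller-matrix image."""
    w = design_matrix(config)
    if np.linalg.matrix_rank(w, tol=1e-10) < 16:
        raise ValueError(
            "acquisition design matrix is rank-deficient; the Mueller matrix "
            "would not be recoverable — choose a different r1_step_deg "
            f"(current: {config.r1_step_deg} deg) or retardance"
        )
    h, wid = mm.shape
    vec = mm.elements.reshape(16, h * wid)  # row-major (i, j) order
    frames = (w @ vec).reshape(config.n_frames, h, wid) * config.intensity_scale
    return FrameSet(
        frames=frames,
        r1_angles_deg=config.r1_angles_deg,
        r2_angles_deg=config.r2_angles_deg,
        config=config,
    )


@dataclass
class FourierCoefficients:
    """Truncated Fourier series of the intensity signal vs retarder phase."""

    alpha0: float
    alpha: np.ndarray  # (n_max,) cosine coefficients, n = 1..n_max
    beta: np.ndarray  # (n_max,) sine coefficients
    residual: float  # rms misfit at the sample points

    @property
    def n_max(self) -> int:
        return len(self.alpha)

    def evaluate(self, phase_rad: np.ndarray) -> np.ndarray:
        phase_rad = np.asarray(phase_rad, dtype=float)
        n = np.arange(1, self.n_max + 1)
        arg = np.outer(phase_rad, n)
        return (
            self.alpha0
            + np.cos(arg) @ self.alpha
            + np.sin(arg) @ self.beta
        )


def fit_fourier_coefficients(
    intensity: Sequence[float],
    phase_rad: Sequence[float] | None = None,
    n_max: int = 12,
    config: AcquisitionConfig | None = None,
) -> FourierCoefficients:
    """Least-squares fit of I = a0 + sum_n (an cos(n x) + bn sin(n x)).

    ``phase_rad`` is the retarder phase x per sample. When omitted, it is
    derived from ``config`` (default :class:`AcquisitionConfig`) as twice
    the R1 angle, reflecting the doubled angular rate at which polarization
    states repeat during a rotation cycle.
    """
    intensity = np.asarray(intensity, dtype=float)
    if phase_rad is None:
        cfg = config or AcquisitionConfig(n_frames=max(len(intensity), 16))
        phase_rad = 2.0 * np.deg2rad(cfg.r1_angles_deg[: len(intensity)])
    phase_rad = np.asarray(phase_rad, dtype=float)
    n_params = 2 * n_max + 1
    if len(intensity) < n_params:
        raise ValueError(
            f"underdetermined fit: {len(intensity)} samples for {n_params} "
            f"Fourier parameters (n_max={n_max})"
        )
    n = np.arange(1, n_max + 1)
    arg = np.outer(phase_rad, n)
    design = np.hstack([np.ones((len(phase_rad), 1)), np.cos(arg), np.sin(arg)])
    coef, *_ = np.linalg.lstsq(design, intensity, rcond=None)
    resid = float(np.sqrt(np.mean((design @ coef - intensity) ** 2)))
    return FourierCoefficients(
        alpha0=float(coef[0]),
        alpha=coef[1 : n_max + 1],
        beta=coef[n_max + 1 :],
        residual=resid,
    )


def reconstruct_mm(frames: FrameSet, config: AcquisitionConfig | None = None) -> MMImage:
    """Recover the per-pixel Mueller matrix from DRR intensity frames.

    Solves the stacked (n_frames x 16) linear system by pseudoinverse at
    every pixel. Returns the unnormalized image; the per-pixel rms misfit
    is stored in ``metadata['residual_map']``.
    """
    config = config or frames.config
    w = np.stack(
        [
            measurement_row(r1, r2, config)
            for r1, r2 in zip(frames.r1_angles_deg, frames.r2_angles_deg)
        ]
    )
    if np.linalg.matrix_rank(w, tol=1e-10) < 16:
        raise ValueError(
            "acquisition design matrix is rank-deficient; reconstruction is "
            "impossible — choose a different r1_step_deg or retardance"
        )
    if np.any(frames.frames < 0):
        logger.warning(
            "negative intensities in %d pixels; proceeding with least squares",
            int(np.sum(np.any(frames.frames < 0, axis=0))),
        )
    n, h, wid = frames.frames.shape
    y = frames.frames.reshape(n, h * wid) / config.intensity_scale
    vec = np.linalg.pinv(w) @ y
    resid = np.sqrt(np.mean((w @ vec - y) ** 2, axis=0)).reshape(h, wid)
    return MMImage(
        elements=vec.reshape(4, 4, h, wid),
        normalized=False,
        provenance="reconstructed",
        metadata={"residual_map": resid},
    )


def normalize_by_m11(mm: MMImage, eps_fraction: float = 1e-6) -> MMImage:
    """Divide every channel pixelwise by M11, masking near-zero M11 pixels.

    Pixels where |M11| < ``eps_fraction`` x max|M11| become NaN in all
    channels and are excluded from downstream statistics.
    """
    m11 = mm.channel((1, 1))
    eps = eps_fraction * np.max(np.abs(m11)) if np.any(m11) else eps_fraction
    bad = np.abs(m11) < eps
    if np.any(bad):
        logger.warning("masking %d pixels with |M11| below threshold", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        elements = mm.elements / m11[None, None, :, :]
    elements[:, :, bad] = np.nan
    out = MMImage(
        elements=elements,
        normalized=True,
        incidence_theta=mm.incidence_theta,
        provenance=mm.provenance,
        metadata=dict(mm.metadata),
    )
    out.metadata["masked_pixels"] = int(bad.sum())
    return out
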