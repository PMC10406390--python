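"""End-to-end analysis pipeline: generate/load -> reconstruct -> sample -> analyze.

For every incidence angle theta the pipeline produces the Mueller-matrix
image (synthesized, reconstructed from DRR frames, or loaded), extracts the
16 azimuthal ring curves, and computes curve statistics, peak/valley
metrics, FDHs, harmonic spectra with the square-wave coefficient Cs, and a
periodicity classification against each element's undistorted family. The
per-(theta, element) results are collected into one summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import io as mmio
from .drr import AcquisitionConfig, normalize_by_m11, reconstruct_mm, render_frames
from .harmonics import (
    DEFAULT_CS_INDEX_MAP,
    classify_periodicity,
    cs_from_spectrum,
    harmonic_amplitudes,
)
from .image import ALL_ELEMENTS, MMImage, element_name
from .phantom import (
    FOUR_PERIODIC_ELEMENTS,
    PhantomParams,
    element_group,
    generate_phantom_mm,
)
from .ring import extract_all_curves
from .stats import compute_fdh, curve_kurtosis, curve_mean, find_peaks_valleys

__all__ = ["PipelineConfig", "ThetaResult", "run_pipeline", "analyze_mm"]

logger = logging.getLogger(__name__)

#: classification expected for each element family at normal incidence
EXPECTED_CLASS = {
    "diagonal": "non-periodic",
    "weak": "non-periodic",
    "two-periodic": "two-periodic",
    "four-periodic": "four-periodic",
}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; every default is echoed at run start."""

    mode: str = "synthetic"  # synthetic | from-frames | from-mm
    thetas: Sequence[float] = (0.0,)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    simulate_drr: bool = False  # synthetic mode: round-trip through the DRR model
    ring_radius: float | None = None  # default: phantom ring radius
    ring_half_width: float = 5.0  # analysis ring, inside the painted annulus
    n_samples: int = 360
    prominence_fraction: float = 0.05
    smooth_window: int = 5
    fdh_bins: int = 256
    fdh_range: tuple = (-1.0, 1.0)
    n_harmonics: int = 16
    cs_index_map: dict = field(default_factory=lambda: dict(DEFAULT_CS_INDEX_MAP))
    input_paths: Dict[float, str] = field(default_factory=dict)  # theta -> path
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d and not isinstance(d["phantom"], PhantomParams):
            d["phantom"] = PhantomParams.from_dict(d["phantom"])
        if "acquisition" in d and not isinstance(d["acquisition"], AcquisitionConfig):
            d["acquisition"] = AcquisitionConfig(**d["acquisition"])
        if "thetas" in d:
            d["thetas"] = [float(t) for t in d["thetas"]]
        if "fdh_range" in d:
            d["fdh_range"] = tuple(d["fdh_range"])
        if "cs_index_map" in d:
            d["cs_index_map"] = {int(k): int(v) for k, v in d["cs_index_map"].items()}
        if "input_paths" in d:
            d["input_paths"] = {float(k): str(v) for k, v in d["input_paths"].items()}
        return cls(**d)


@dataclass
class ThetaResult:
    """All analysis products for one incidence angle."""

    theta: float
    mm: MMImage
    curves: dict
    spectra: dict
    peaksets: dict
    fdhs: dict
    records: List[dict]


def _phantom_for_theta(config: PipelineConfig, theta: float, index: int) -> PhantomParams:
    base = config.phantom
    return PhantomParams(
        image_size=base.image_size,
        center=base.center,
        ring_radius=base.ring_radius,
        ring_half_width=base.ring_half_width,
        incidence_theta=theta,
        coefficients=base.coefficients,
        profile=base.profile,
        distortion=base.distortion,
        noise_sigma=base.noise_sigma,
        seed=int(config.seed) + index,
    )


def _acquire_mm(config: PipelineConfig, theta: float, index: int) -> MMImage:
    if config.mode == "synthetic":
        params = _phantom_for_theta(config, theta, index)
        if config.simulate_drr:
            raw = generate_phantom_mm(params, normalized=False)
            frames = render_frames(raw, config.acquisition)
            mm = reconstruct_mm(frames, config.acquisition)
            mm.incidence_theta = theta
            return normalize_by_m11(mm)
        return generate_phantom_mm(params, normalized=True)
    path = config.input_paths.get(theta)
    if path is None or not Path(path).exists():
        raise FileNotFoundError(
            f"mode {config.mode!r} requires an existing input path for theta={theta}"
        )
    if config.mode == "from-frames":
        frames = mmio.read_frames_tiff(path)
        mm = reconstruct_mm(frames)
        mm.incidence_theta = theta
        return normalize_by_m11(mm)
    if config.mode == "from-mm":
        mm = mmio.read_mm_tiff(path)
        mm.incidence_theta = theta
        return mm if mm.normalized else normalize_by_m11(mm)
    raise ValueError(f"unknown pipeline mode {config.mode!r}")


def analyze_mm(mm: MMImage, config: PipelineConfig | None = None) -> ThetaResult:
    """Run the per-image analysis stage (curves, statistics, spectra, FDHs)."""
    config = config or PipelineConfig()
    theta = mm.incidence_theta if mm.incidence_theta is not None else float("nan")
    radius = config.ring_radius
    if radius is None:
        radius = config.phantom.ring_radius
    half_width = config.ring_half_width
    center = config.phantom.center

    curves = extract_all_curves(
        mm,
        center=center,
        radius=radius,
        half_width=half_width,
        n_samples=config.n_samples,
    )

    annulus = _annulus_mask(mm, center, radius, half_width)
    records: List[dict] = []
    spectra, peaksets, fdhs = {}, {}, {}
    for idx in ALL_ELEMENTS:
        name = element_name(idx)
        curve = curves[name]
        group = element_group(idx)
        rec: Dict = {"theta": theta, "element": name, "group": group}

        rec["mean"] = curve_mean(curve)
        try:
            rec["kurtosis"] = curve_kurtosis(curve)
        except ValueError:
            logger.warning(
                "kurtosis undefined for constant %s curve at theta=%s", name, theta
            )
            rec["kurtosis"] = float("nan")

        spectrum = harmonic_amplitudes(curve, n_max=config.n_harmonics)
        for n in range(1, 9):
            rec[f"A{n}"] = spectrum.amplitude(n)
        if idx in FOUR_PERIODIC_ELEMENTS:
            spectrum.cs = cs_from_spectrum(spectrum, config.cs_index_map)
            rec["cs"] = spectrum.cs
        else:
            rec["cs"] = float("nan")
        rec["classification"] = classify_periodicity(
            spectrum, expected=EXPECTED_CLASS[group]
        )
        spectra[name] = spectrum

        peakset = find_peaks_valleys(
            curve,
            prominence_fraction=config.prominence_fraction,
            smooth_window=config.smooth_window,
        )
        rec["n_peaks"] = peakset.n_peaks
        rec["pp_mean"] = (
            float(np.mean(peakset.pp_values)) if len(peakset.pp_values) else float("nan")
        )
        rec["pv_mean"] = (
            float(np.mean(peakset.pv_values)) if len(peakset.pv_values) else float("nan")
        )
        rec["pp_gap"] = peakset.pp_gap
        peaksets[name] = peakset

        fdhs[name] = compute_fdh(
            mm, idx, roi_mask=annulus, n_bins=config.fdh_bins,
            value_range=config.fdh_range,
        )
        rec["fdh_centroid"] = fdhs[name].centroid
        records.append(rec)

    return ThetaResult(
        theta=theta, mm=mm, curves=curves, spectra=spectra,
        peaksets=peaksets, fdhs=fdhs, records=records,
    )


def _annulus_mask(mm, center, radius, half_width):
    h, w = mm.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cy, cx = center
    rows, cols = np.mgrid[0:h, 0:w]
    r = np.hypot(rows - cy, cols - cx)
    return np.abs(r - radius) <= half_width


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis for every theta and build the summary table.

    Returns ``{"summary": DataFrame, "results": {theta: ThetaResult}}``;
    when ``config.out_dir`` is set, also writes one subdirectory per theta
    (MM TIFF, curves CSV, spectra CSV, stats CSV) plus summary.csv and the
    run configuration as run_config.yaml.
    """
    logger.info("pipeline config: %s", asdict(config))
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    results: Dict[float, ThetaResult] = {}
    all_records: List[dict] = []
    for k, theta in enumerate(config.thetas):
        try:
            mm = _acquire_mm(config, theta, k)
            result = analyze_mm(mm, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at theta={theta} (mode={config.mode}): {exc}"
            ) from exc
        results[theta] = result
        all_records.extend(result.records)
        if out_dir:
            sub = out_dir / f"theta_{theta:g}"
            sub.mkdir(exist_ok=True)
            mmio.write_mm_tiff(mm, sub / "mm.tiff")
            mmio.write_curves_csv(result.curves, sub / "curves.csv")
            _write_spectra_csv(result, sub / "spectra.csv")
            pd.DataFrame(result.records).to_csv(sub / "stats.csv", index=False)

    summary = pd.DataFrame(all_records)
    if out_dir:
        summary.to_csv(out_dir / "summary.csv", index=False)
        mmio.dump_yaml(_config_dict(config), out_dir / "run_config.yaml")
    return {"summary": summary, "results": results}


def _write_spectra_csv(result: ThetaResult, path: Path) -> None:
    rows = []
    for name, sp in result.spectra.items():
        for n in range(1, sp.n_max + 1):
            rows.append(
                {
                    "element": name,
                    "n": n,
                    "An": sp.amplitude(n),
                    "phi_deg": float(sp.phases_deg[n - 1]),
                    "cs": sp.cs if sp.cs is not None else float("nan"),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["phantom"] = config.phantom.to_dict()
    return d
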