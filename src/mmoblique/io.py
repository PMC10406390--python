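"""Disk formats: multi-page TIFF image stacks, CSV curve tables, YAML configs.

A Mueller-matrix image is stored as a 16-page TIFF (row-major page order
m11, m12, ..., m44) with a JSON sidecar carrying the generation/acquisition
metadata; a frame set as an n_frames-page TIFF with the retarder angles in
its sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .drr import AcquisitionConfig, FrameSet
from .image import ALL_ELEMENTS, MMImage, element_name
from .ring import AzimuthalCurve

__all__ = [
    "write_mm_tiff",
    "read_mm_tiff",
    "write_frames_tiff",
    "read_frames_tiff",
    "write_curves_csv",
    "read_curves_csv",
    "load_yaml",
    "dump_yaml",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mm_tiff(mm: MMImage, path) -> Path:
    """Write a 16-page TIFF (m11..m44) with a JSON metadata sidecar."""
    path = Path(path)
    pages = np.stack([mm.channel(idx) for idx in ALL_ELEMENTS]).astype(np.float64)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "kind": "mm_image",
        "page_order": [element_name(idx) for idx in ALL_ELEMENTS],
        "normalized": mm.normalized,
        "incidence_theta": mm.incidence_theta,
        "provenance": mm.provenance,
        "metadata": _jsonable(mm.metadata),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_mm_tiff(path) -> MMImage:
    path = Path(path)
    pages = tifffile.imread(path).astype(float)
    if pages.ndim != 3 or pages.shape[0] != 16:
        raise ValueError(
            f"{path} is not a 16-page Mueller-matrix TIFF (shape {pages.shape})"
        )
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return MMImage(
        elements=pages.reshape(4, 4, *pages.shape[1:]),
        normalized=bool(meta.get("normalized", False)),
        incidence_theta=meta.get("incidence_theta"),
        provenance=meta.get("provenance", str(path)),
        metadata=meta.get("metadata", {}),
    )


def write_frames_tiff(frames: FrameSet, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, frames.frames.astype(np.float64), photometric="minisblack")
    meta = {
        "kind": "drr_frames",
        "r1_angles_deg": frames.r1_angles_deg.tolist(),
        "r2_angles_deg": frames.r2_angles_deg.tolist(),
        "config": _jsonable(frames.config.__dict__),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_frames_tiff(path) -> FrameSet:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"frame stack {path} has no JSON sidecar with retarder angles"
        )
    meta = json.loads(sidecar.read_text())
    config = AcquisitionConfig(**meta["config"])
    return FrameSet(
        frames=stack,
        r1_angles_deg=np.asarray(meta["r1_angles_deg"]),
        r2_angles_deg=np.asarray(meta["r2_angles_deg"]),
        config=config,
    )


def write_curves_csv(curves: Mapping[str, AzimuthalCurve], path) -> Path:
    """Write all element curves as CSV with columns azimuth_deg, m11..m44."""
    path = Path(path)
    first = next(iter(curves.values()))
    data = {"azimuth_deg": first.azimuths_deg}
    for idx in ALL_ELEMENTS:
        name = element_name(idx)
        if name in curves:
            data[name] = curves[name].values
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_curves_csv(path) -> Dict[str, AzimuthalCurve]:
    path = Path(path)
    df = pd.read_csv(path)
    if "azimuth_deg" not in df.columns:
        raise ValueError(f"{path} has no 'azimuth_deg' column")
    az = df["azimuth_deg"].to_numpy(dtype=float)
    out: Dict[str, AzimuthalCurve] = {}
    for col in df.columns:
        if col == "azimuth_deg":
            continue
        idx = (int(col[1]), int(col[2]))
        out[col] = AzimuthalCurve(
            element_index=idx,
            azimuths_deg=az,
            values=df[col].to_numpy(dtype=float),
            provenance={"source": str(path)},
        )
    return out


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(obj), fh, sort_keys=False)
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
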