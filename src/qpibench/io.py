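"""TIFF + JSON-sidecar persistence for phase images and interferograms.

Phase maps are written as 32-bit float TIFFs with OPD in nm; interferograms
as 16-bit unsigned TIFFs in counts.  Each image gets a ``<name>.json``
sidecar carrying the metadata that the arrays cannot (pixel size, wavelength,
exposure, carrier parameters), so a file round-trip is lossless up to the
16-bit quantisation of counts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .core import Interferogram, PhaseImage

__all__ = [
    "write_phase_tiff",
    "read_phase_tiff",
    "write_interferogram_tiff",
    "read_interferogram_tiff",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_phase_tiff(phase: PhaseImage, path: str | Path,
                     extra: dict[str, Any] | None = None) -> Path:
    """Write an OPD map as 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, phase.opd.astype(np.float32))
    meta = {"pixel_size_um": phase.pixel_size, "wavelength_nm": phase.wavelength}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_phase_tiff(path: str | Path) -> PhaseImage:
    path = Path(path)
    opd = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    return PhaseImage(opd, meta["pixel_size_um"], meta.get("wavelength_nm", 590.0))


def write_interferogram_tiff(interf: Interferogram, path: str | Path) -> Path:
    """Write counts as 16-bit TIFF plus a sidecar with carrier metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.round(interf.counts).astype(np.uint16))
    meta = dict(interf.metadata)
    meta["exposure_time_ms"] = interf.exposure_time
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_interferogram_tiff(path: str | Path) -> Interferogram:
    path = Path(path)
    counts = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    exposure = meta.pop("exposure_time_ms")
    threshold = meta.get("saturation_threshold", np.inf)
    return Interferogram(
        counts=counts,
        exposure_time=exposure,
        saturated_mask=counts >= threshold,
        metadata=meta,
    )
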