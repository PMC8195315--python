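"""Named configuration presets and YAML round-tripping.

The ``paper_baseline`` preset is the reference acquisition of the benchmark:
condenser NA 0.09 under a 0.45 NA objective, 1.9 μW/mm² × 100 ms
(0.19 μJ/mm² fluence, ≈0.73 μJ over the 3.86 mm² field), in focus, with the
detector targeting a mean of 3000 counts and tallying saturation at 3545.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .core import AcquisitionConfig, DetectorConfig, SphereSpec

__all__ = ["paper_baseline", "save_config", "load_config"]


def paper_baseline() -> tuple[AcquisitionConfig, DetectorConfig]:
    """The baseline acquisition and detector settings (see module docstring)."""
    return AcquisitionConfig(), DetectorConfig()


def save_config(
    path: str | Path,
    acq: AcquisitionConfig,
    det: DetectorConfig,
    spheres: list[SphereSpec] | None = None,
) -> Path:
    """Write acquisition/detector (and optional sphere specs) to YAML."""
    doc = {
        "acquisition": dataclasses.asdict(acq),
        "detector": dataclasses.asdict(det),
    }
    if spheres is not None:
        doc["spheres"] = [dataclasses.asdict(s) for s in spheres]
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_config(
    path: str | Path,
) -> tuple[AcquisitionConfig, DetectorConfig, list[SphereSpec]]:
    """Read a YAML config written by :func:`save_config` (or hand-edited)."""
    doc = yaml.safe_load(Path(path).read_text())
    acq = AcquisitionConfig(**doc.get("acquisition", {}))
    det = DetectorConfig(**doc.get("detector", {}))
    spheres = [SphereSpec(**s) for s in doc.get("spheres", [])]
    return acq, det, spheres
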