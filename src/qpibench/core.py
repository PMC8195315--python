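"""Core data containers for the QPI benchmarking pipeline.

The central currency is the :class:`PhaseImage`: a 2-D optical pathlength
difference (OPD) field in nanometres, carried together with the lateral pixel
size (μm/pixel) and illumination wavelength (nm).  Detector-side data live in
:class:`Interferogram` (carrier-fringe counts images) and the acquisition /
detector settings in :class:`AcquisitionConfig` / :class:`DetectorConfig`.

Units convention, used consistently everywhere:

* OPD in nm, lateral coordinates and pixel size in μm, wavelength in nm;
* OPD gradients in nm/μm;
* exposure time in ms, irradiance in μW/mm², illuminated area in mm²;
* detector signal in counts (gain fixed at 1 count per photoelectron).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "PhaseImage",
    "Interferogram",
    "GradientField",
    "SphereSpec",
    "AcquisitionConfig",
    "DetectorConfig",
]


@dataclass
class PhaseImage:
    """A 2-D OPD map in nm with pixel-size (μm) and wavelength (nm) metadata."""

    opd: np.ndarray
    pixel_size: float
    wavelength: float = 590.0

    def __post_init__(self) -> None:
        self.opd = np.asarray(self.opd, dtype=np.float64)
        if self.opd.ndim != 2:
            raise ValueError("opd must be a 2-D array")
        if not np.all(np.isfinite(self.opd)):
            raise ValueError("opd contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.opd.shape  # type: ignore[return-value]

    def copy(self) -> "PhaseImage":
        return PhaseImage(self.opd.copy(), self.pixel_size, self.wavelength)

    def with_opd(self, opd: np.ndarray) -> "PhaseImage":
        """Return a new PhaseImage sharing this image's metadata."""
        return PhaseImage(opd, self.pixel_size, self.wavelength)


@dataclass
class Interferogram:
    """Detector counts image carrying carrier-fringe modulation.

    ``saturated_mask`` marks pixels at or above the detector saturation
    threshold (the count level used to tally saturated pixels, which may sit
    just below the hard full-well clip).  ``metadata`` records the carrier
    and shear parameters needed for demodulation plus an ``aliasing`` flag
    raised by the simulator when the encoded phase gradient exceeds π.
    """

    counts: np.ndarray
    exposure_time: float
    saturated_mask: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        self.saturated_mask = np.asarray(self.saturated_mask, dtype=bool)
        if self.saturated_mask.shape != self.counts.shape:
            raise ValueError("saturated_mask shape mismatch")


@dataclass
class GradientField:
    """Two orthogonal OPD spatial derivatives (nm/μm) on a common grid."""

    gx: np.ndarray
    gy: np.ndarray
    pixel_size: float
    wavelength: float = 590.0

    def __post_init__(self) -> None:
        self.gx = np.asarray(self.gx, dtype=np.float64)
        self.gy = np.asarray(self.gy, dtype=np.float64)
        if self.gx.shape != self.gy.shape:
            raise ValueError("gx and gy must have the same shape")
        if not (np.all(np.isfinite(self.gx)) and np.all(np.isfinite(self.gy))):
            raise ValueError("gradients contain non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class SphereSpec:
    """Ground truth for one homogeneous microsphere.

    The refractive-index step Δn = n_sphere − n_medium drives the projected
    OPD; all the bead/medium combinations considered here have
    n_sphere > n_medium, so a negative Δn must be opted into explicitly.
    """

    center_x: float          # μm
    center_y: float          # μm
    diameter: float          # μm
    n_sphere: float
    n_medium: float
    allow_negative_dn: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.delta_n < 0 and not self.allow_negative_dn:
            raise ValueError(
                f"negative delta_n ({self.delta_n:.4g}) for sphere at "
                f"({self.center_x:.1f}, {self.center_y:.1f}); "
                "set allow_negative_dn=True if intended"
            )

    @property
    def delta_n(self) -> float:
        return self.n_sphere - self.n_medium

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def peak_opd(self) -> float:
        """Analytic OPD at the sphere centre, in nm (OPD = Δn·D)."""
        return 1000.0 * self.delta_n * self.diameter


@dataclass(frozen=True)
class AcquisitionConfig:
    """Microscope-side acquisition settings.

    Defaults are the baseline: 590 nm illumination, condenser NA 0.09 under a
    0.45 NA objective, 1.9 μW/mm² irradiance for 100 ms (0.19 μJ/mm² fluence)
    over a 3.86 mm² field, in focus.
    """

    wavelength: float = 590.0        # nm
    condenser_na: float = 0.09
    objective_na: float = 0.45
    irradiance: float = 1.9          # μW/mm²
    exposure_time: float = 100.0     # ms
    defocus_z: float = 0.0           # μm
    illuminated_area: float = 3.86   # mm²

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        if self.condenser_na <= 0:
            raise ValueError("condenser_na must be positive")
        if self.objective_na <= 0:
            raise ValueError("objective_na must be positive")

    @property
    def na_ratio(self) -> float:
        return self.condenser_na / self.objective_na

    @property
    def coherence_exceeded(self) -> bool:
        """True when the illumination NA exceeds the objective NA.

        Such configurations are representable but flagged: shearing
        reconstruction degrades sharply once spatial coherence is lost.
        """
        return self.condenser_na > self.objective_na

    def replace(self, **kw: Any) -> "AcquisitionConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class DetectorConfig:
    """CCD and carrier-fringe parameters of the shearing interferometer model.

    ``full_well_counts`` is the ceiling of the detector's linear range (counts
    clip there); ``saturation_threshold`` is the count level used to tally
    saturated pixels, sitting just below the clip.  ``calib_*`` fields define
    the reference acquisition at which the fringe mean equals
    ``target_mean_counts``; counts scale linearly with
    exposure × irradiance × NA² relative to that reference.
    """

    full_well_counts: float = 3600.0
    saturation_threshold: float = 3545.0
    target_mean_counts: float = 3000.0
    read_noise_sd: float = 5.0         # counts rms
    fringe_contrast: float = 0.15      # total modulation depth, in (0, 1]
    carrier_period_px: float = 8.0
    shear_s: float = 1.3               # μm (2 pixels at the default sampling)
    gradient_blur_px: float = 1.5      # optical MTF of the fringe relay (σ, px)
    rng_seed: int = 0
    shot_noise: bool = True
    calib_exposure_ms: float = 100.0
    calib_irradiance: float = 1.9      # μW/mm²
    calib_na: float = 0.09

    def __post_init__(self) -> None:
        if not (0 < self.saturation_threshold <= self.full_well_counts):
            raise ValueError("need 0 < saturation_threshold <= full_well_counts")
        if not (0 < self.fringe_contrast <= 1):
            raise ValueError("fringe_contrast must be in (0, 1]")
        if self.carrier_period_px < 3:
            raise ValueError("carrier_period_px must be >= 3 (sampling)")
        if self.shear_s <= 0:
            raise ValueError("shear_s must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    def replace(self, **kw: Any) -> "DetectorConfig":
        return replace(self, **kw)

    def noise_free(self) -> "DetectorConfig":
        """Copy with shot and read noise disabled (clipping retained)."""
        return replace(self, shot_noise=False, read_noise_sd=0.0)
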