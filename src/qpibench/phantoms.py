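"""Ground-truth phantom generators: microspheres and cell-like fields.

A homogeneous sphere of diameter D and index step Δn immersed in a medium
projects an optical pathlength difference

    OPD(r) = 1000 · Δn · 2·sqrt((D/2)² − r²)   [nm],   r < D/2,

so the peak at the centre is Δn·D (in μm, hence the factor 1000 to nm) and
the integrated OPD equals Δn times the geometric volume, Δn·(π/6)·D³.
Cell-like objects are modelled as super-Gaussian OPD blobs with peak phase
shifts in the range typical of adherent (~500 nm) to loosely adherent round
(~900 nm) cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PhaseImage, SphereSpec

__all__ = [
    "sphere_opd_map",
    "multi_sphere_opd_map",
    "brightfield_phantom",
    "cell_field",
    "CellField",
    "random_sphere_population",
]

DEFAULT_PIXEL_SIZE = 0.65  # μm/px, 10x-class sampling (>100 px across 67.7 μm)


def _grids(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    return np.meshgrid(x, y)


def _check_in_bounds(spec: SphereSpec, shape: tuple[int, int], pixel_size: float) -> None:
    ny, nx = shape
    r = spec.radius
    if (spec.center_x - r < 0 or spec.center_y - r < 0
            or spec.center_x + r > nx * pixel_size
            or spec.center_y + r > ny * pixel_size):
        raise ValueError(
            f"sphere (D={spec.diameter:.1f} μm at "
            f"({spec.center_x:.1f}, {spec.center_y:.1f}) μm) does not fit "
            f"inside a {ny}x{nx} image at {pixel_size} μm/px"
        )


def sphere_opd_map(
    spec: SphereSpec,
    shape: tuple[int, int],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    wavelength: float = 590.0,
) -> PhaseImage:
    """Analytic projected-OPD image of a single sphere.

    Raises if the sphere footprint leaves the image; warns when the sampling
    is coarser than D/10 (diameter and peak estimates degrade).
    """
    _check_in_bounds(spec, shape, pixel_size)
    if pixel_size > spec.diameter / 10.0:
        warnings.warn(
            f"pixel_size {pixel_size} μm is coarse for D={spec.diameter} μm "
            "(fewer than 10 pixels across the sphere)",
            stacklevel=2,
        )
    xx, yy = _grids(shape, pixel_size)
    r2 = (xx - spec.center_x) ** 2 + (yy - spec.center_y) ** 2
    chord2 = np.clip(spec.radius**2 - r2, 0.0, None)
    opd = 1000.0 * spec.delta_n * 2.0 * np.sqrt(chord2)
    return PhaseImage(opd, pixel_size, wavelength)


def multi_sphere_opd_map(
    specs: list[SphereSpec],
    shape: tuple[int, int],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    wavelength: float = 590.0,
) -> PhaseImage:
    """Sum of analytic sphere OPD maps (spheres are assumed non-overlapping)."""
    opd = np.zeros(shape, dtype=np.float64)
    for spec in specs:
        opd += sphere_opd_map(spec, shape, pixel_size, wavelength).opd
    return PhaseImage(opd, pixel_size, wavelength)


def brightfield_phantom(
    specs: SphereSpec | list[SphereSpec],
    shape: tuple[int, int],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    background: float = 200.0,
    contrast: float = 150.0,
    edge_blur_px: float = 2.0,
) -> np.ndarray:
    """Brightfield-style intensity phantom: dark disks on a bright field.

    The transmitted-light optics are not modelled; a disk at the sphere's
    geometric footprint with a Gaussian edge blur stands in for the
    low-contrast brightfield appearance used for diameter measurement.
    """
    if isinstance(specs, SphereSpec):
        specs = [specs]
    xx, yy = _grids(shape, pixel_size)
    img = np.full(shape, background, dtype=np.float64)
    disk = np.zeros(shape, dtype=np.float64)
    for spec in specs:
        _check_in_bounds(spec, shape, pixel_size)
        r2 = (xx - spec.center_x) ** 2 + (yy - spec.center_y) ** 2
        disk[r2 <= spec.radius**2] = 1.0
    if edge_blur_px > 0:
        disk = ndimage.gaussian_filter(disk, edge_blur_px)
    return img - contrast * disk


def random_sphere_population(
    n_spheres: int = 20,
    diameter_range: tuple[float, float] = (63.0, 75.0),
    delta_n: float = 0.0187,
    n_medium: float = 1.468,
    rng_seed: int = 0,
) -> list[SphereSpec]:
    """Draw a PMMA-in-mineral-oil-like bead population.

    Diameters are uniform over the vendor's 63–75 μm range; Δn defaults to
    0.0187, the midpoint of the 0.0154–0.0220 spread observed across material
    lots. Positions are not assigned here (see the sweep harness, which tiles
    beads into fields).
    """
    rng = np.random.default_rng(rng_seed)
    diameters = rng.uniform(*diameter_range, size=n_spheres)
    return [
        SphereSpec(0.0, 0.0, float(d), n_medium + delta_n, n_medium)
        for d in diameters
    ]


@dataclass
class CellField:
    """A synthetic cell-field phantom with per-cell ground truth."""

    phase: PhaseImage
    labels: np.ndarray               # int labels, 0 = background
    peak_opds: np.ndarray            # nm, one per cell
    radii: np.ndarray                # μm, one per cell
    centers: np.ndarray              # (n, 2) μm, (x, y)

    @property
    def optical_volume(self) -> float:
        """Ground-truth whole-field optical volume in μm³."""
        return float(self.phase.opd.sum() * self.phase.pixel_size**2 / 1000.0)


def cell_field(
    n_cells: int,
    peak_opd_range: tuple[float, float] = (500.0, 900.0),
    radius_range: tuple[float, float] = (8.0, 15.0),
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    rng_seed: int = 0,
    wavelength: float = 590.0,
    order: int = 3,
    max_tries: int = 200,
) -> CellField:
    """Place non-overlapping super-Gaussian cell blobs with ground truth.

    Each cell is ``peak · exp(−(r/R)^(2·order))`` (order 3 by default: a flat
    interior with a steep rim, the qualitative OPD morphology of round cells).
    Peak OPDs are drawn uniformly from ``peak_opd_range``; the ground-truth
    label of a cell covers pixels where its OPD exceeds max(5 nm, 1% of peak).

    Raises RuntimeError if non-overlapping placement fails after bounded
    retries.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    lo, hi = peak_opd_range
    if lo <= 0 or hi < lo:
        raise ValueError("peak_opd_range must be positive and ordered")
    rlo, rhi = radius_range
    if rlo <= 0 or rhi < rlo:
        raise ValueError("radius_range must be positive and ordered")

    rng = np.random.default_rng(rng_seed)
    ny, nx = shape
    w, h = nx * pixel_size, ny * pixel_size
    xx, yy = _grids(shape, pixel_size)

    opd = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)
    peaks, radii, centers = [], [], []

    margin = 3.0  # μm clearance between cell rims
    for i in range(n_cells):
        radius = float(rng.uniform(rlo, rhi))
        peak = float(rng.uniform(lo, hi))
        placed = False
        for _ in range(max_tries):
            # keep the full footprint (to ~1.3 R where OPD falls below 1%)
            pad = 1.4 * radius
            if 2 * pad >= min(w, h):
                raise RuntimeError(
                    f"cannot place cell of radius {radius:.1f} μm without "
                    f"overlapping the border of a {w:.0f}x{h:.0f} μm field"
                )
            cx = float(rng.uniform(pad, w - pad))
            cy = float(rng.uniform(pad, h - pad))
            ok = all(
                np.hypot(cx - px, cy - py) > 1.4 * (radius + pr) + margin
                for (px, py), pr in zip(centers, radii)
            )
            if ok:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n_cells} without overlap "
                f"after {max_tries} tries; reduce n_cells or radii"
            )
        r = np.hypot(xx - cx, yy - cy)
        profile = peak * np.exp(-((r / radius) ** (2 * order)))
        opd += profile
        labels[profile > max(5.0, 0.01 * peak)] = i + 1
        peaks.append(peak)
        radii.append(radius)
        centers.append((cx, cy))

    return CellField(
        phase=PhaseImage(opd, pixel_size, wavelength),
        labels=labels,
        peak_opds=np.asarray(peaks),
        radii=np.asarray(radii),
        centers=np.asarray(centers).reshape(-1, 2),
    )
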