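"""Optical and detector forward model.

Degrades ground-truth OPD fields the way the acquisition chain does:

* ``defocus_phase`` — scalar angular-spectrum propagation of the complex
  field exp(i·2π·OPD/λ) over a defocus distance z, with evanescent
  frequencies zeroed and the phase recovered by 2-D unwrapping;
* ``partial_coherent_opd`` — incoherent average of tilted-illumination
  reconstructions sampled on a Fibonacci disk inside the condenser NA,
  each tilt seeing the objective pupil shifted by the illumination angle
  (so larger condenser apertures clip more of the object spectrum, and a
  tilt under defocus produces the expected z·tanθ lateral shift);
* ``synthesize_interferogram`` — two orthogonal sinusoidal carriers whose
  local phases are proportional to the OPD gradients (shear s), scaled to
  the detector's count budget, with Poisson shot noise, Gaussian read noise
  and full-well clipping.

This deliberately simple carrier model reproduces what the benchmark needs —
reference subtraction, saturation bias, and demodulation behaviour — without
modelling the proprietary Hartmann-mask diffraction orders.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase

from .core import AcquisitionConfig, DetectorConfig, Interferogram, PhaseImage

__all__ = [
    "defocus_phase",
    "partial_coherent_opd",
    "synthesize_interferogram",
    "illumination_energy",
    "fibonacci_disk",
    "counts_scale",
    "fringe_visibility",
]

MAX_DEFOCUS_UM = 150.0  # sanity bound; the benchmark sweeps −100..+10 μm

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_disk(n: int, radius: float) -> np.ndarray:
    """n low-discrepancy points covering a disk of the given radius.

    Deterministic; used to sample illumination tilts within the condenser NA.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.zeros((1, 2))
    k = np.arange(n)
    r = radius * np.sqrt((k + 0.5) / n)
    th = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _freq_grids(shape: tuple[int, int], pixel_size: float):
    ny, nx = shape
    fx = np.fft.fftfreq(nx, d=pixel_size)  # cycles/μm
    fy = np.fft.fftfreq(ny, d=pixel_size)
    return np.meshgrid(fx, fy)


def _propagate(
    field: np.ndarray,
    pixel_size: float,
    wavelength_nm: float,
    z: float,
    tilt: tuple[float, float] = (0.0, 0.0),
    pupil_na: float | None = None,
) -> np.ndarray:
    """Angular-spectrum propagation, optionally under tilted illumination.

    ``tilt`` is the (sin θx, sin θy) of the illumination direction; the object
    spectrum then sits at physical frequencies f + tilt/λ, which is where both
    the defocus kernel and the (optional) objective pupil are evaluated.
    Evanescent components are zeroed explicitly.
    """
    lam = wavelength_nm / 1000.0  # μm
    fxx, fyy = _freq_grids(field.shape, pixel_size)
    fx_p = fxx + tilt[0] / lam
    fy_p = fyy + tilt[1] / lam
    spec = np.fft.fft2(field)
    if pupil_na is not None:
        spec = spec * (fx_p**2 + fy_p**2 <= (pupil_na / lam) ** 2)
    if z != 0.0:
        kz2 = 1.0 / lam**2 - fx_p**2 - fy_p**2
        prop_mask = kz2 > 0
        kernel = np.where(prop_mask, np.exp(2j * np.pi * z * np.sqrt(np.clip(kz2, 0, None))), 0.0)
        spec = spec * kernel
    out = np.fft.ifft2(spec)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("propagation produced non-finite values")
    return out


def _field_to_opd(field: np.ndarray, wavelength_nm: float) -> np.ndarray:
    """Unwrapped phase of a complex field, converted to OPD (nm), median-zeroed."""
    phi = unwrap_phase(np.angle(field))
    opd = phi * wavelength_nm / (2.0 * np.pi)
    return opd - np.median(opd)


def defocus_phase(phase: PhaseImage, z: float) -> PhaseImage:
    """Propagate an OPD map by a defocus distance z (μm).

    Positive z moves the object away from the objective. z = 0 returns the
    input unchanged. The result is defined up to a global constant, fixed by
    zeroing the median (which keeps an empty background at 0 for phantoms
    occupying less than half the field).
    """
    if abs(z) > MAX_DEFOCUS_UM:
        raise ValueError(f"|z| = {abs(z)} μm exceeds the {MAX_DEFOCUS_UM} μm bound")
    if z == 0.0:
        return phase.copy()
    field = np.exp(2j * np.pi * phase.opd / phase.wavelength)
    out = _propagate(field, phase.pixel_size, phase.wavelength, z)
    return phase.with_opd(_field_to_opd(out, phase.wavelength))


def partial_coherent_opd(
    phase: PhaseImage,
    acq: AcquisitionConfig,
    n_angles: int = 37,
    rng_seed: int | None = None,
) -> PhaseImage:
    """Partially coherent image of an OPD map at the given acquisition.

    Averages the OPD reconstructed under ``n_angles`` illumination tilts
    sampled on a Fibonacci disk of radius condenser_na. Each tilt's spectrum
    is clipped by the objective pupil (shifted by the tilt) and propagated by
    ``acq.defocus_z``. The coherent in-focus limit (condenser_na → 0, z = 0)
    reduces to the pupil-filtered input.

    ``rng_seed`` is accepted for interface symmetry; the tilt set is a
    deterministic low-discrepancy sequence, so the result does not depend on
    it. If the condenser NA exceeds the objective NA the result's
    ``reconstruction_may_fail`` attribute is set (off-axis tilts then miss
    the pupil entirely, as with real shearing systems losing coherence).
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    tilts = fibonacci_disk(n_angles, acq.condenser_na)
    if n_angles == 1:
        tilts = np.zeros((1, 2))
    field = np.exp(2j * np.pi * phase.opd / phase.wavelength)
    acc = np.zeros(phase.shape, dtype=np.float64)
    n_used = 0
    for sx, sy in tilts:
        if np.hypot(sx, sy) > acq.objective_na:
            continue  # tilt falls outside the pupil: no image forms
        out = _propagate(
            field,
            phase.pixel_size,
            phase.wavelength,
            acq.defocus_z,
            tilt=(sx, sy),
            pupil_na=acq.objective_na,
        )
        acc += _field_to_opd(out, phase.wavelength)
        n_used += 1
    if n_used == 0:
        raise ValueError(
            "no illumination angle passed the objective pupil "
            f"(condenser NA {acq.condenser_na} vs objective NA {acq.objective_na})"
        )
    result = phase.with_opd(acc / n_used)
    result.reconstruction_may_fail = acq.coherence_exceeded  # type: ignore[attr-defined]
    return result


def fringe_visibility(condenser_na: float, shear_um: float, wavelength_nm: float) -> float:
    """Shear-fringe visibility under an extended (partially coherent) source.

    The two sheared field copies interfere with a tilt-dependent phase offset
    2π·s·sinθ/λ; averaging over a uniform source disk of half-angle NA gives
    the classic Airy-type factor V = 2·J1(x)/x with x = 2π·s·NA/λ. Visibility
    falls with condenser NA and hits zero at x ≈ 3.83 — the coherence limit
    beyond which fringes (and hence phase reconstruction) vanish. Negative
    lobes are clamped to zero: past the first null the carrier is effectively
    lost.
    """
    from scipy.special import j1

    x = 2.0 * np.pi * shear_um * condenser_na / (wavelength_nm / 1000.0)
    if x == 0.0:
        return 1.0
    return float(max(2.0 * j1(x) / x, 0.0))


def counts_scale(acq: AcquisitionConfig, det: DetectorConfig) -> float:
    """Linear count-budget factor relative to the calibration acquisition.

    Counts scale with exposure × irradiance × (condenser NA)²: opening the
    aperture collects more light, which is why the benchmark rescales
    exposure to hold the mean image intensity constant across NA settings.
    """
    return (
        (acq.exposure_time / det.calib_exposure_ms)
        * (acq.irradiance / det.calib_irradiance)
        * (acq.condenser_na / det.calib_na) ** 2
    )


def synthesize_interferogram(
    phase: PhaseImage,
    det: DetectorConfig,
    acq: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> Interferogram:
    """Render an OPD map into a carrier-fringe detector image.

    counts = clip(Poisson(I0·scale·[1 + (c/2)cos(2πx/p + φx)
                                      + (c/2)cos(2πy/p + φy)]) + read noise,
                  0, full_well)

    with φ{x,y} = (2π·s/λ)·∂OPD/∂{x,y}. I0 is calibrated so the mean equals
    ``target_mean_counts`` at the calibration acquisition. A gradient phase
    beyond π per shear cannot be encoded unambiguously; such frames carry
    ``metadata['aliasing'] = True`` rather than being silently corrupted.
    """
    p = det.carrier_period_px
    ny, nx = phase.shape
    if p > min(nx, ny) / 4:
        raise ValueError("carrier period not resolvable on this grid")
    gy, gx = np.gradient(phase.opd, phase.pixel_size)  # nm/μm
    if det.gradient_blur_px > 0:
        # the relay optics band-limit the fringe pattern: without this blur an
        # object edge of near-infinite slope splatters spectral energy across
        # both sidebands and corrupts the demodulation position-dependently
        gx = ndimage.gaussian_filter(gx, det.gradient_blur_px)
        gy = ndimage.gaussian_filter(gy, det.gradient_blur_px)
    phi_x = 2.0 * np.pi * det.shear_s * gx / phase.wavelength
    phi_y = 2.0 * np.pi * det.shear_s * gy / phase.wavelength
    aliasing = bool(max(np.abs(phi_x).max(), np.abs(phi_y).max()) > np.pi)

    xx = np.arange(nx)[None, :]
    yy = np.arange(ny)[:, None]
    c = det.fringe_contrast * fringe_visibility(
        acq.condenser_na, det.shear_s, phase.wavelength)
    fringe = (
        1.0
        + (c / 2.0) * np.cos(2.0 * np.pi * xx / p + phi_x)
        + (c / 2.0) * np.cos(2.0 * np.pi * yy / p + phi_y)
    )
    intensity = det.target_mean_counts * counts_scale(acq, det) * fringe

    if det.shot_noise or det.read_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(det.rng_seed)
        counts = intensity
        if det.shot_noise:
            counts = rng.poisson(np.clip(intensity, 0, None)).astype(np.float64)
        if det.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, det.read_noise_sd, size=counts.shape)
    else:
        counts = intensity
    counts = np.clip(counts, 0.0, det.full_well_counts)
    saturated = counts >= det.saturation_threshold

    return Interferogram(
        counts=counts,
        exposure_time=acq.exposure_time,
        saturated_mask=saturated,
        metadata={
            "carrier_period_px": p,
            "shear_um": det.shear_s,
            "fringe_contrast": c,
            "pixel_size_um": phase.pixel_size,
            "wavelength_nm": phase.wavelength,
            "full_well_counts": det.full_well_counts,
            "saturation_threshold": det.saturation_threshold,
            "aliasing": aliasing,
        },
    )


def illumination_energy(
    acq: AcquisitionConfig | None = None,
    *,
    irradiance: float | None = None,
    exposure_time: float | None = None,
    illuminated_area: float | None = None,
) -> tuple[float, float]:
    """Total illumination energy (μJ) and fluence (μJ/mm²) of an acquisition.

    fluence = irradiance × exposure; energy = irradiance × area × exposure.
    E.g. 1.9 μW/mm² for 100 ms gives 0.19 μJ/mm², and 7.5 μW total over
    3.86 mm² for 135 μs gives ≈0.001 μJ. Accepts either an
    :class:`AcquisitionConfig` or the three raw values (allowing, e.g., a
    zero exposure, which an AcquisitionConfig forbids).
    """
    if acq is not None:
        irradiance = acq.irradiance
        exposure_time = acq.exposure_time
        illuminated_area = acq.illuminated_area
    if irradiance is None or exposure_time is None or illuminated_area is None:
        raise TypeError("provide an AcquisitionConfig or all three raw values")
    if irradiance <= 0 or illuminated_area <= 0:
        raise ValueError("irradiance and illuminated_area must be positive")
    if exposure_time < 0:
        raise ValueError("exposure_time must be non-negative")
    fluence = irradiance * exposure_time / 1000.0      # μJ/mm²
    energy = fluence * illuminated_area                # μJ
    return energy, fluence
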