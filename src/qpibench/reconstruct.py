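"""Phase reconstruction from carrier-fringe interferograms.

The inverse of the forward detector model: each orthogonal carrier sideband
is extracted with a Gaussian window in the frequency domain, demodulated to
baseband, and its wrapped phase converted to an OPD gradient via the shear
relation g = φ·λ/(2π·s).  The two gradients are then integrated with a
least-squares Fourier (Frankot–Chellappa-style) solver on an even/odd mirror
extension, which avoids the periodicity artefacts of a bare FFT inversion.
No phase unwrapping is applied to the gradients: the simulator flags frames
whose gradient phase exceeds π per shear, and the benchmark's objects stay
within that bound at instrument-like shear.
"""

from __future__ import annotations

import numpy as np

from .core import DetectorConfig, GradientField, Interferogram, PhaseImage

__all__ = [
    "demodulate_gradients",
    "integrate_gradients",
    "reference_subtract",
    "background_offset_correct",
    "saturation_fraction",
    "reconstruct_opd",
    "BORDER_PX",
]

# apodization band excluded from downstream statistics (demodulation edge roll-off)
BORDER_PX = 8


def _extract_sideband(
    spectrum: np.ndarray,
    fxx: np.ndarray,
    fyy: np.ndarray,
    carrier: tuple[float, float],
    sigma_f: float,
    support_f: float,
) -> np.ndarray:
    """Window one carrier sideband and return the demodulated complex image.

    Gaussian of width ``sigma_f`` with hard support truncation at radius
    ``support_f`` (the carrier half-spacing): the truncation removes
    cross-talk from the orthogonal carrier and the DC term entirely (a pure
    carrier then demodulates to a numerically exact constant phase).
    """
    d2 = (fxx - carrier[0]) ** 2 + (fyy - carrier[1]) ** 2
    window = np.exp(-d2 / (2.0 * sigma_f**2)) * (d2 <= support_f**2)
    return np.fft.ifft2(spectrum * window)


def demodulate_gradients(
    interf: Interferogram,
    det: DetectorConfig | None = None,
    window_sigma_factor: float = 0.75,
) -> GradientField:
    """Recover the two OPD gradients (nm/μm) from a fringe image.

    Carrier parameters are taken from the interferogram metadata (written by
    the simulator); ``det`` may override them. The sideband window is a
    Gaussian of width ``window_sigma_factor`` times the carrier frequency
    (default 0.75), hard-truncated at half the carrier spacing to exclude
    the orthogonal carrier and the DC term. Raises if no sideband energy is
    found at the expected carrier.
    """
    meta = interf.metadata
    p = float(det.carrier_period_px if det is not None else meta["carrier_period_px"])
    s = float(det.shear_s if det is not None else meta["shear_um"])
    lam = float(meta["wavelength_nm"])
    pixel_size = float(meta["pixel_size_um"])

    counts = interf.counts
    ny, nx = counts.shape
    spectrum = np.fft.fft2(counts - counts.mean())
    fx = np.fft.fftfreq(nx)  # cycles/px
    fy = np.fft.fftfreq(ny)
    fxx, fyy = np.meshgrid(fx, fy)
    f_c = 1.0 / p
    sigma_f = f_c * window_sigma_factor

    # carrier presence check: sideband peak must rise above the spectral floor
    mag = np.abs(spectrum)
    floor = np.median(mag) + 1e-30
    for carrier in ((f_c, 0.0), (0.0, f_c)):
        near = (fxx - carrier[0]) ** 2 + (fyy - carrier[1]) ** 2 <= (f_c / 4) ** 2
        if mag[near].max() < 10.0 * floor:
            raise ValueError(
                f"carrier not found near frequency {carrier} cycles/px"
            )

    xx = np.arange(nx)[None, :]
    yy = np.arange(ny)[:, None]
    side_x = _extract_sideband(spectrum, fxx, fyy, (f_c, 0.0), sigma_f, f_c / 2.0)
    side_y = _extract_sideband(spectrum, fxx, fyy, (0.0, f_c), sigma_f, f_c / 2.0)
    phi_x = np.angle(side_x * np.exp(-2j * np.pi * xx / p))
    phi_y = np.angle(side_y * np.exp(-2j * np.pi * yy / p))

    scale = lam / (2.0 * np.pi * s)  # nm/μm per radian
    return GradientField(gx=phi_x * scale, gy=phi_y * scale,
                         pixel_size=pixel_size, wavelength=lam)


def integrate_gradients(g: GradientField, mirror_extend: bool = True) -> PhaseImage:
    """Least-squares integration of a gradient field to an OPD map.

    Frankot–Chellappa in the Fourier domain, by default on an even/odd
    mirror extension (the extension makes the implied surface even, removing
    wrap-around artefacts for non-periodic fields). With
    ``mirror_extend=False`` the solver runs on the bare grid, where it is an
    exact pseudo-inverse of the spectral gradient for periodic fields. The
    additive constant is fixed by zeroing the median, which is robust
    whenever objects cover less than half the field; downstream,
    ``background_offset_correct`` refines it against a background mask.
    """
    gx_px = g.gx * g.pixel_size  # nm per pixel step
    gy_px = g.gy * g.pixel_size
    ny, nx = gx_px.shape

    if mirror_extend:
        # even surface extension: gx odd in x/even in y, gy even in x/odd in y
        gx_e = np.block([
            [gx_px, -gx_px[:, ::-1]],
            [gx_px[::-1, :], -gx_px[::-1, ::-1]],
        ])
        gy_e = np.block([
            [gy_px, gy_px[:, ::-1]],
            [-gy_px[::-1, :], -gy_px[::-1, ::-1]],
        ])
    else:
        gx_e, gy_e = gx_px, gy_px

    fx = np.fft.fftfreq(gx_e.shape[1])
    fy = np.fft.fftfreq(gx_e.shape[0])
    fxx, fyy = np.meshgrid(fx, fy)
    denom = (2.0 * np.pi) ** 2 * (fxx**2 + fyy**2)
    denom[0, 0] = 1.0
    num = -2j * np.pi * (fxx * np.fft.fft2(gx_e) + fyy * np.fft.fft2(gy_e))
    z_hat = num / denom
    z_hat[0, 0] = 0.0
    z = np.real(np.fft.ifft2(z_hat))[:ny, :nx]
    z -= np.median(z)
    return PhaseImage(z, g.pixel_size, g.wavelength)


def reconstruct_opd(
    interf: Interferogram,
    det: DetectorConfig | None = None,
) -> PhaseImage:
    """Demodulate and integrate an interferogram into an OPD map."""
    return integrate_gradients(demodulate_gradients(interf, det))


def reference_subtract(sample: PhaseImage, reference: PhaseImage) -> PhaseImage:
    """Element-wise sample − reference OPD.

    The reference acquisition of background medium removes common-mode
    instrument wavefront (tilt, offset); shapes and pixel sizes must match.
    """
    if sample.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: sample {sample.shape} vs reference {reference.shape}"
        )
    if sample.pixel_size != reference.pixel_size:
        raise ValueError("pixel size mismatch between sample and reference")
    return sample.with_opd(sample.opd - reference.opd)


def background_offset_correct(
    phase: PhaseImage,
    object_mask: np.ndarray,
) -> PhaseImage:
    """Subtract the mean OPD of non-object pixels uniformly.

    After correction the background mean is exactly zero. A tilted (non-flat)
    background keeps its tilt — only the uniform offset is removed. Requires
    at least 1% of pixels to be background.
    """
    object_mask = np.asarray(object_mask, dtype=bool)
    if object_mask.shape != phase.shape:
        raise ValueError("object_mask shape mismatch")
    background = ~object_mask
    if background.sum() < 0.01 * background.size:
        raise ValueError("fewer than 1% background pixels; cannot estimate offset")
    return phase.with_opd(phase.opd - phase.opd[background].mean())


def saturation_fraction(interf: Interferogram, threshold: float | None = None) -> float:
    """Fraction of pixels at or above the saturation threshold, in [0, 1]."""
    if threshold is None:
        threshold = float(interf.metadata.get("saturation_threshold", np.inf))
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(np.mean(interf.counts >= threshold))
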