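"""Fringe demodulation, gradient integration, and OPD bookkeeping."""

import numpy as np
import pytest
from scipy import ndimage

from qpibench import (
    AcquisitionConfig,
    DetectorConfig,
    GradientField,
    Interferogram,
    PhaseImage,
    background_offset_correct,
    demodulate_gradients,
    integrate_gradients,
    reconstruct_opd,
    reference_subtract,
    saturation_fraction,
    synthesize_interferogram,
)

PIXEL = 0.65


@pytest.fixture(scope="module")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="module")
def det_nf():
    return DetectorConfig().noise_free()


class TestDemodulation:
    def test_flat_field_yields_zero_gradients(self, acq, det_nf):
        flat = PhaseImage(np.zeros((256, 256)), PIXEL)
        g = demodulate_gradients(synthesize_interferogram(flat, det_nf, acq))
        assert np.abs(g.gx).max() < 1e-6
        assert np.abs(g.gy).max() < 1e-6

    def test_linear_ramp_recovered_uniformly(self, acq, det_nf):
        slope = 3.0  # nm/μm
        xx = (np.arange(256) + 0.5) * PIXEL
        ramp = PhaseImage(np.tile(slope * xx, (256, 1)), PIXEL)
        g = demodulate_gradients(synthesize_interferogram(ramp, det_nf, acq))
        interior = g.gx[32:-32, 32:-32]
        assert np.abs(interior / slope - 1.0).max() < 0.01
        assert np.abs(g.gy[32:-32, 32:-32]).max() < 0.05

    def test_sphere_gradients_match_analytic_derivative(
            self, acq, det_nf, centered_sphere, centered_sphere_phase):
        g = demodulate_gradients(
            synthesize_interferogram(centered_sphere_phase, det_nf, acq))
        # analytic ∂OPD/∂x of the chord profile, compared at the resolution
        # the carrier channel supports (one carrier period): the sideband
        # support truncation leaves zero-mean band-edge ripple that averages
        # out in integration and under matched smoothing
        xx, yy = np.meshgrid((np.arange(256) + 0.5) * PIXEL,
                             (np.arange(256) + 0.5) * PIXEL)
        dx = xx - centered_sphere.center_x
        dy = yy - centered_sphere.center_y
        r2 = dx**2 + dy**2
        R = centered_sphere.radius
        gx_true = np.where(r2 < R**2,
                           -2000.0 * centered_sphere.delta_n * dx
                           / np.sqrt(np.clip(R**2 - r2, 1e-9, None)), 0.0)
        sigma = 8.0  # px, the carrier period
        a = ndimage.gaussian_filter(g.gx, sigma)
        b = ndimage.gaussian_filter(gx_true, sigma)
        inner = r2 < (0.7 * R) ** 2
        rms = np.sqrt(np.mean((a[inner] - b[inner]) ** 2))
        scale = np.sqrt(np.mean(b[inner] ** 2))
        assert rms / scale < 0.02

    def test_missing_carrier_raises(self):
        counts = np.full((128, 128), 500.0)
        interf = Interferogram(
            counts=counts, exposure_time=100.0,
            saturated_mask=np.zeros((128, 128), bool),
            metadata={"carrier_period_px": 8.0, "shear_um": 1.3,
                      "wavelength_nm": 590.0, "pixel_size_um": PIXEL})
        with pytest.raises(ValueError, match="carrier not found"):
            demodulate_gradients(interf)


class TestIntegration:
    def test_zero_gradients_give_zero_surface(self):
        g = GradientField(np.zeros((64, 64)), np.zeros((64, 64)), PIXEL)
        z = integrate_gradients(g)
        assert np.abs(z.opd).max() == 0.0

    def test_exact_pseudo_inverse_for_periodic_fields(self):
        # spectral-derivative gradients of a smooth periodic surface must
        # integrate back to the surface up to an additive constant
        n = 128
        k = np.arange(n)
        surface = 100.0 * (np.cos(2 * np.pi * 3 * k / n)[None, :]
                           * np.sin(2 * np.pi * 2 * k / n)[:, None])
        spec = np.fft.fft2(surface)
        fx, fy = np.meshgrid(np.fft.fftfreq(n), np.fft.fftfreq(n))
        gx = np.real(np.fft.ifft2(2j * np.pi * fx * spec)) / PIXEL
        gy = np.real(np.fft.ifft2(2j * np.pi * fy * spec)) / PIXEL
        z = integrate_gradients(GradientField(gx, gy, PIXEL),
                                mirror_extend=False)
        diff = z.opd - surface
        assert np.abs(diff - diff.mean()).max() < 1e-6

    def test_sphere_cap_gradients_integrate_to_peak(self, acq, det_nf,
                                                    centered_sphere_phase):
        recon = reconstruct_opd(
            synthesize_interferogram(centered_sphere_phase, det_nf, acq))
        peak_true = centered_sphere_phase.opd.max()
        assert abs(recon.opd.max() - peak_true) / peak_true < 0.02


class TestReferenceHandling:
    def test_sample_equals_reference_gives_zero(self, centered_sphere_phase):
        out = reference_subtract(centered_sphere_phase, centered_sphere_phase)
        assert not out.opd.any()

    def test_common_mode_tilt_rejected(self, centered_sphere_phase):
        tilt = PhaseImage(
            np.tile(0.5 * np.arange(256) * PIXEL, (256, 1)), PIXEL)
        sample = centered_sphere_phase.with_opd(
            centered_sphere_phase.opd + tilt.opd)
        out = reference_subtract(sample, tilt)
        assert np.allclose(out.opd, centered_sphere_phase.opd, atol=1e-9)

    def test_shape_mismatch_rejected(self, centered_sphere_phase):
        small = PhaseImage(np.zeros((64, 64)), PIXEL)
        with pytest.raises(ValueError, match="shape"):
            reference_subtract(centered_sphere_phase, small)

    def test_independent_noise_adds_in_quadrature(self):
        rng = np.random.default_rng(7)
        sigma = 3.0
        a = PhaseImage(rng.normal(0, sigma, (128, 128)), PIXEL)
        b = PhaseImage(rng.normal(0, sigma, (128, 128)), PIXEL)
        out = reference_subtract(a, b)
        assert out.opd.std() == pytest.approx(sigma * np.sqrt(2), rel=0.10)

    def test_full_roundtrip_invariant_to_reference_tilt_and_offset(
            self, acq, det_nf, centered_sphere_phase):
        # an instrument-residual wavefront tilt+offset shared by sample and
        # reference must not move the measured peak OPD by more than 0.1%
        xx = (np.arange(256) + 0.5) * PIXEL
        wavefront = 20.0 + 0.05 * np.tile(xx, (256, 1))
        flat = centered_sphere_phase.with_opd(np.zeros((256, 256)))
        peaks = []
        for base in (np.zeros((256, 256)), wavefront):
            sample = synthesize_interferogram(
                centered_sphere_phase.with_opd(centered_sphere_phase.opd + base),
                det_nf, acq)
            reference = synthesize_interferogram(
                flat.with_opd(base), det_nf, acq)
            recon = reference_subtract(reconstruct_opd(sample),
                                       reconstruct_opd(reference))
            peaks.append(recon.opd.max())
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.001


class TestBackgroundOffset:
    def test_constant_image_with_empty_mask_zeroed(self):
        phase = PhaseImage(np.full((64, 64), 7.0), PIXEL)
        out = background_offset_correct(phase, np.zeros((64, 64), bool))
        assert np.allclose(out.opd, 0.0)

    def test_sphere_plus_offset_restored(self, centered_sphere_phase):
        shifted = centered_sphere_phase.with_opd(centered_sphere_phase.opd + 50.0)
        mask = centered_sphere_phase.opd > 0
        out = background_offset_correct(shifted, mask)
        assert np.allclose(out.opd, centered_sphere_phase.opd, atol=1e-9)
        assert out.opd[~mask].mean() == pytest.approx(0.0, abs=1e-9)

    def test_tilted_background_keeps_tilt_but_zero_mean(self):
        tilt = np.tile(np.linspace(-5, 5, 64), (64, 1))
        out = background_offset_correct(PhaseImage(tilt + 9.0, PIXEL),
                                        np.zeros((64, 64), bool))
        assert out.opd.mean() == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(out.opd) == pytest.approx(np.ptp(tilt), abs=1e-9)

    def test_no_background_pixels_rejected(self, centered_sphere_phase):
        with pytest.raises(ValueError, match="background"):
            background_offset_correct(centered_sphere_phase,
                                      np.ones((256, 256), bool))


class TestSaturationFraction:
    def _interf(self, counts):
        return Interferogram(counts=counts, exposure_time=100.0,
                             saturated_mask=counts >= 3545,
                             metadata={"saturation_threshold": 3545.0})

    def test_extremes(self):
        assert saturation_fraction(self._interf(np.full((32, 32), 100.0))) == 0.0
        assert saturation_fraction(self._interf(np.full((32, 32), 3600.0))) == 1.0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(3)
        counts = rng.uniform(0, 4000, (64, 64))
        frac = saturation_fraction(self._interf(counts), threshold=3545.0)
        assert frac == np.sum(counts >= 3545.0) / counts.size

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            saturation_fraction(self._interf(np.zeros((8, 8))), threshold=-1.0)
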