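"""Forward-model a bead into carrier fringes and reconstruct it back.

Exercises the full measurement chain: OPD → two-carrier shearing
interferogram (with detector noise) → sideband demodulation → least-squares
gradient integration → reference subtraction → background offset correction.
"""

import numpy as np
from scipy import ndimage

from qpibench import (
    AcquisitionConfig, BORDER_PX, DetectorConfig, SphereSpec,
    background_offset_correct, isodata_threshold, reconstruct_opd,
    reference_subtract, sphere_opd_map, synthesize_interferogram,
)

spec = SphereSpec(166.4, 166.4, 67.7, 1.488, 1.468)
truth = sphere_opd_map(spec, (512, 512), 0.65)
acq = AcquisitionConfig()          # NA 0.09, 1.9 uW/mm^2 x 100 ms, in focus
det = DetectorConfig()             # mean 3000 counts, shot + read noise

rng = np.random.default_rng(0)
sample = synthesize_interferogram(truth, det, acq, rng=rng)
reference = synthesize_interferogram(truth.with_opd(np.zeros(truth.shape)),
                                     det, acq, rng=rng)
print(f"sample fringes: mean {sample.counts.mean():.0f} counts, "
      f"saturated fraction {sample.saturated_mask.mean():.4f}")

recon = reference_subtract(reconstruct_opd(sample), reconstruct_opd(reference))
rough = ndimage.binary_dilation(recon.opd > isodata_threshold(recon.opd),
                                iterations=3)
recon = background_offset_correct(recon, rough)

peak_err = 100.0 * (recon.opd.max() - spec.peak_opd) / spec.peak_opd
print(f"reconstructed peak OPD: {recon.opd.max():.1f} nm "
      f"(truth {spec.peak_opd:.1f} nm, error {peak_err:+.2f} %)")
interior = np.zeros(recon.shape, bool)
interior[BORDER_PX:-BORDER_PX, BORDER_PX:-BORDER_PX] = True
print(f"background residual   : {recon.opd[interior & ~rough].std():.2f} nm rms "
      f"(interior, {BORDER_PX}-px apodization band excluded)")
# A percent-level peak error is the expected single-frame performance at the
# baseline settings. The ~30 nm background residual is smooth, low-frequency
# undulation: gradient integration amplifies phase noise as 1/f, the dominant
# error source of shearing reconstructions at low fringe contrast.
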