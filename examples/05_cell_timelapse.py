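"""Time-lapse dry-mass monitoring of a synthetic cell field under
acquisition variants.

Cell-like blobs (peak phase shifts 500-900 nm) are imaged repeatedly through
the full pipeline under a baseline and a dimmed-illumination variant; the
whole-field segmented area, dry mass (optical volume / specific refractive
increment) and mass density are compared per frame against baseline.
"""

from qpibench import AcquisitionConfig, run_cell_timelapse

variants = {
    "baseline": AcquisitionConfig(),
    "half_energy": AcquisitionConfig(irradiance=1.9 * 0.5),
}
result = run_cell_timelapse({"n_cells": 8, "shape": (384, 384)}, n_frames=4,
                            acq_variants=variants, seed=11, n_angles=9)

cols = ["value", "area_mean", "mass_mean", "area_pct_change",
        "mass_pct_change", "density_pct_change"]
print(result.table[cols].round(3).to_string(index=False))
print(f"ground-truth field optical volume: "
      f"{result.metadata['ground_truth_ov_um3']:.0f} um^3")
# Halving the illumination energy doubles the shot-noise share but leaves
# the demodulated phase unbiased, so area/mass/density changes stay at the
# percent level; SEM columns quantify frame-to-frame spread.
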