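# qpibench

Synthetic benchmarking of a quantitative phase imaging (QPI) measurement
chain with microsphere reference phantoms.

QPI reports the optical pathlength difference (OPD, in nm) that light
accumulates crossing a transparent object, which makes cell dry mass
measurable: for a homogeneous sphere the peak OPD equals Δn·D (Δn the
refractive-index step to the medium, D the diameter), the summed OPD over
the object is its *optical volume* OV = Δn·(π/6)·D³, and dry mass follows
as m = OV/α with the specific refractive increment α = 1.8·10⁻⁴ m³/kg.
Microspheres with known Δn and D therefore serve as reference materials: if
an instrument recovers their Δn and OV, its settings are fit for measuring
cells. `qpibench` rebuilds that protocol entirely in simulation, for people
developing or validating QPI pipelines:

* **phantoms** — analytic bead OPD maps, brightfield-style disk images,
  and cell-like fields with ground-truth masks;
* **forward model** — partial spatial coherence (tilt averaging inside the
  condenser NA, objective pupil, shear-fringe visibility 2·J₁(x)/x),
  angular-spectrum defocus, and a carrier-fringe detector with shot/read
  noise and full-well saturation;
* **reconstruction** — Fourier sideband demodulation of the two carriers,
  least-squares (Frankot–Chellappa) gradient integration, reference
  subtraction, background offset correction;
* **segmentation** — IsoData (iterative intermeans) thresholding,
  Chan–Vese-style active contours with a contraction bias, and a
  gradient-threshold cell segmenter;
* **morphometry & sweeps** — Δn, optical volume, dry mass, density, percent
  error; orchestrated sensitivity sweeps over condenser NA, illumination
  energy, and focus, plus a cell time-lapse analysis, with admissible
  parameter ranges and CSV/JSON reports.

## Worked example

Measure four simulated PMMA-like beads (Δn = 0.0187, D ∈ [63, 75] μm) at the
baseline acquisition — condenser NA 0.09, 0.19 μJ/mm² fluence, in focus,
mean 3000 detector counts (`examples/03_measure_beads.py`):

```python
import numpy as np
from qpibench import AcquisitionConfig, DetectorConfig
from qpibench.phantoms import random_sphere_population
from qpibench.sweeps import measure_sphere_field, tile_sphere_fields

population = random_sphere_population(n_spheres=4, rng_seed=7)
field = tile_sphere_fields(population)[0]
df, info = measure_sphere_field(field, AcquisitionConfig(), DetectorConfig(),
                                np.random.default_rng(7))
```

prints

```
 D_bf_um  true_D_um  opd_max_nm  delta_n  true_delta_n    ov_um3
 73.8417    73.7666   1366.6345   0.0185        0.0187 3893.0577
 70.5025    70.5011   1326.0656   0.0188        0.0187 3389.9366
 72.2957    72.3082   1336.6470   0.0185        0.0187 3634.1184
 65.6998    65.7025   1215.8304   0.0185        0.0187 2661.0102

per-bead |delta_n error|: max 1.13 %, mean 0.94 %
field diagnostics: mean 3000 counts, saturation fraction 0.0000
```

`D_bf_um` is the diameter measured on the matching brightfield phantom
(IsoData), `opd_max_nm` the median-filtered peak OPD of the reconstructed
phase image, and `delta_n = opd_max/(1000·D)` the recovered index step —
each bead lands within the 5% calibration bound of the 0.0187 ground truth.
`ov_um3` is the summed OPD over the segmented bead (for the largest bead,
theory gives Δn·π/6·D³ ≈ 3930 μm³, a −0.9% deviation).

The other scripts in `examples/` walk the remaining capabilities: phantom
generation against the closed forms, a noisy reconstruction round trip, a
condenser-NA sweep with admissible-range extraction, and a cell time-lapse
with dry-mass readouts.

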