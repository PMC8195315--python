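# Methods

`qpibench` benchmarks a quantitative phase imaging (QPI) measurement chain on
synthetic microsphere and cell phantoms. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments can and cannot say about real instruments.

## The measurement model

**Objects.** A homogeneous sphere of diameter *D* (μm) and refractive-index
step Δn = n_sphere − n_medium immersed in a matched medium projects an
optical pathlength difference

    OPD(r) = 1000 · Δn · 2·√((D/2)² − r²)   [nm],  r < D/2,

so the peak is Δn·D and the integrated OPD ("optical volume") is
OV = Δn·(π/6)·D³. The default bead population imitates PMMA beads in mineral
oil: D ~ Uniform(63, 75) μm, Δn = 0.0187 (the midpoint of the 0.0154–0.0220
spread observed across material lots), λ = 590 nm, sampled at 0.65 μm/pixel
(10×-class sampling, >100 pixels across a bead; the instrument pixel size is
not published, so this is a package choice). Cell-like objects are
super-Gaussian blobs of order 3 (flat interior, steep rim) with peak phase
shifts drawn uniformly from 500–900 nm — the adherent-to-round-cell range —
and radii 8–15 μm.

**Illumination and coherence.** Partial spatial coherence is modelled by
incoherent averaging of 37 tilted-illumination reconstructions, the tilts
sampled on a deterministic Fibonacci disk of radius equal to the condenser
NA. Each tilt's spectrum is clipped by the objective pupil (NA 0.45) shifted
by the tilt, then propagated by the defocus distance with the
angular-spectrum kernel (evanescent components zeroed); a tilt under defocus
thereby produces the expected z·tanθ lateral shift. Separately, the shear
fringes lose visibility under an extended source: the two sheared field
copies interfere with a tilt-dependent phase offset 2π·s·sinθ/λ, and
averaging over the source disk gives V = 2·J₁(x)/x with x = 2π·s·NA/λ. With
the default shear this visibility crosses zero near condenser NA 0.28 — the
model's coherence limit, beyond which no carrier (and hence no
reconstruction) exists. The condenser-NA sensitivity of the benchmark is
carried almost entirely by this visibility loss (signal-to-noise), with a
small deterministic contribution from the pupil clipping.

**Detector and fringes.** The shearing interferogram is simplified to two
orthogonal sinusoidal carriers (period 8 px) whose local phases are
proportional to the OPD gradients: φ = 2π·s·∂OPD/∂x / λ with shear
s = 2 pixels (1.3 μm). The encoded gradients are first blurred by a small
Gaussian MTF (σ 1.5 px) representing the band limit of the fringe-relay
optics; without it, the analytically sharp bead rim (unbounded slope)
splatters spectral energy across both sidebands and corrupts demodulation in
a position-dependent way no real instrument shows. Counts are
I₀·scale·[1 + (c/2)cos(2πx/p + φx) + (c/2)cos(2πy/p + φy)] with Poisson shot
noise (gain 1 count/photoelectron), Gaussian read noise (σ 5 counts), and a
hard clip at the full well. I₀ is calibrated so the mean equals 3000 counts
at the reference acquisition (1.9 μW/mm² × 100 ms at condenser NA 0.09); the
count budget scales linearly with exposure × irradiance × NA².

The published operating points pin the detector constants: mean ≈3000
counts, a saturation-tally threshold of 3545 counts, and ≈50% of pixels
saturated at 1 μJ (≈1.33× the 0.75 μJ baseline energy). These are mutually
consistent only if the linear range ends just above the tally threshold and
the fringe peak sits below it at baseline, hence full well 3600 counts and
fringe contrast 0.15 (fringe peak 3450 at baseline, so the baseline
saturation fraction is ≈0). A frame whose encoded gradient phase exceeds π
per shear carries an `aliasing` flag rather than being silently corrupted.

## Reconstruction

Each carrier sideband is selected in the frequency domain by a Gaussian
window (σ = 0.75 of the carrier frequency) hard-truncated at half the
carrier spacing. The truncation removes DC and cross-carrier leakage
entirely — a pure carrier demodulates to a numerically exact constant — at
the cost of zero-mean band-edge ringing around sharp rims, which averages
out in integration. The wrapped sideband phase is converted to gradients by
λ/(2π·s); no unwrapping is applied (the simulator's aliasing check enforces
the |φ| < π regime). Gradients are integrated with a Frankot–Chellappa
least-squares Fourier solver on an even/odd mirror extension (removing
wrap-around artefacts; a no-extension mode is an exact pseudo-inverse for
periodic fields). The additive constant is fixed by zeroing the median, then
refined by subtracting the mean over IsoData-background pixels after
reference subtraction, exactly zeroing the background mean. An 8-pixel
border band is excluded from downstream statistics. The dominant stochastic
error of the whole chain is low-frequency: integration amplifies gradient
noise as 1/f, producing smooth ±30 nm background undulations at the default
contrast — this, not pixel noise, limits per-bead Δn to a few percent.

## Segmentation and morphometry

* **IsoData** (iterative intermeans on a 256-bin histogram) thresholds
  brightfield-style images; the classic fixed point t ← (mean≤t + mean>t)/2
  is used rather than the FIJI "Default" variant because the fixed point is
  testable against exhaustive bin enumeration.
* **Active contour**: Chan–Vese-type region competition with a contraction
  bias (MATLAB sign convention, positive contracts). The default, −0.8
  (expansive), was calibrated on the analytic bead phantom so the converged
  boundary tracks the faint rim within half a pixel — mirroring the bench
  practice of adjusting this parameter manually on beads and then freezing
  it for a whole sensitivity sweep. A contracting default leaves the
  low-OPD rim outside the contour and biases diameters by >1%.
* **Gradient-threshold (EGT-style) cell segmentation**: threshold the
  gradient-magnitude histogram at a mode-anchored percentile
  (thr = mode + 0.25·(1−greediness)·(P99−mode)) over gradients above a
  2 nm/μm noise floor, close, fill holes, drop objects under 50 μm². The
  absolute floor deliberately breaks exact scale invariance, as a real
  noise floor does. This is a deterministic surrogate with a single
  greediness knob, not a reimplementation of the published EGT algorithm.
* **Morphometry**: Δn = OPD_max/(1000·D) with the peak taken after a 3×3
  median prefilter (default on; the raw maximum is noise-biased upward,
  and the choice is switchable); in the sweep pipeline D comes from the
  matching brightfield phantom (IsoData), as the bench protocol measures
  it, with the phase-mask equivalent diameter kept alongside. Dry mass is
  OV/α with the specific refractive increment α = 1.8·10⁻⁴ m³/kg
  (0.18 μm³/pg); density is mass per segmented area. Percent errors are
  signed internally and reported as magnitudes in figure-style summaries.
  SEM is taken across beads for sphere sweeps and across time points for
  the cell time-lapse.

## Sensitivity sweeps

Sweeps tile the bead population four-per-512²-field and run the full chain
per parameter value with per-condition seeded RNG streams; the deterministic
partial-coherence stage is cached across conditions. For the condenser-NA
sweep the exposure is rescaled by (NA₀/NA)² to hold the mean counts at
target (realized means stay within 1%). The energy sweep scales irradiance
(or exposure) relative to baseline and records saturation fractions and
count histograms; the focus sweep scans defocus with z = 0 as reference
(the bench's manual focusing is replaced by the z = 0 ground truth; no
autofocus is provided). Failed reconstructions — carrier washout at heavy
saturation, visibility collapse at high NA, segmentation finding nothing —
are flagged rows with NaN metrics, never dropped. `admissible_range`
extracts the largest contiguous interval around the baseline within a given
error tolerance. The time-lapse default is 16 frames at desk scale
(configurable to the full 200), with a fixed cell layout, small per-frame
amplitude drift, fresh detector noise per frame, and per-frame percent
changes against the baseline variant averaged with SEM over frames.

## What the synthetic experiments do and do not show

The phantoms have exactly known Δn, geometry, and noise, so tests verify
*pipeline* accuracy: recovery of Δn within the 5% calibration bound at
baseline (measured max per-bead error ≈3–4% with default noise, ≈1.6%
noise-free), brightfield/phase diameter agreement well under 1%, and the
qualitative degradation structure — monotone optical-volume error growth
with condenser NA, |defocus| per side, and saturation fraction; a flat Δn
plateau across energies below saturation; reconstruction failure beyond the
coherence and saturation limits. They do not reproduce instrument-specific
tolerance endpoints (the NA < 0.12, −30…+10 μm focus, <0.8 μJ envelopes are
properties of the physical instrument and material lots), and three model
behaviours differ from the bench in known ways:

* the Δn-vs-saturation onset sits at a saturated-pixel fraction ≈0.9 rather
  than ≈0.5, because symmetrically clipping a fringe crest preserves the
  phase of its carrier fundamental; the physical CCD turns nonlinear
  (asymmetric) earlier;
* the reconstruction-failure NA (≈0.28, the first zero of the visibility
  factor at the default shear) differs from the instrument's ≈0.15, which
  reflects a larger physical shear;
* the cell-area sensitivity to acquisition settings is muted: the surrogate
  EGT recomputes its threshold per image, keeping whole-field area within
  ~1% across energy variants where the bench saw tens of percent, so the
  area-vs-mass robustness ordering is asserted where it is well-posed —
  when extra segmented area is verifiably background-dominated (then area
  inflates ~13% while mass moves ~1%).

## Reproducibility and numerics

Every stochastic operation takes an explicit seed or `numpy` Generator;
fixed seeds give bit-identical phantoms, interferograms, sweep tables, and
report files. Degenerate inputs fail loudly: constant images (IsoData),
empty masks, collapsed contours, missing carriers, spheres out of bounds,
and empty backgrounds all raise with the offending setting named. Desk-scale
problem sizes used throughout the tests — 512² fields, 8–20 beads, 37
illumination angles, 16-frame time-lapses — were chosen so the full suite
exercises every pipeline stage at the fidelity the accuracy bounds require.
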