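"""Acquisition-parameter sensitivity sweeps.

Reproduces the benchmarking protocol end to end on synthetic data: for each
setting of condenser NA, illumination energy, or focus, a bead population is
imaged through the full forward model (partial coherence → defocus →
carrier-fringe detector), reconstructed, segmented with one fixed active
contour parameter, and measured; errors are reported against the baseline
setting (and against the theoretical optical volume of the mean bead).  A
cell-field time-lapse analogue measures whole-field area, dry mass, and mass
density per frame under acquisition variants.  ``admissible_range`` then
extracts the contiguous parameter interval around the baseline within a
given error tolerance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AcquisitionConfig, DetectorConfig, PhaseImage, SphereSpec
from .morphometry import measure_objects, optical_volume
from .optics import illumination_energy, partial_coherent_opd, synthesize_interferogram
from .phantoms import (
    brightfield_phantom,
    cell_field,
    multi_sphere_opd_map,
    random_sphere_population,
)
from .reconstruct import (
    background_offset_correct,
    reconstruct_opd,
    reference_subtract,
    saturation_fraction,
)
from .segment import (
    active_contour_segment,
    filter_objects,
    gradient_threshold_segment,
    isodata_threshold,
    segmentation_from_labels,
)

__all__ = [
    "SweepResult",
    "tile_sphere_fields",
    "measure_sphere_field",
    "run_na_sweep",
    "run_energy_sweep",
    "run_focus_sweep",
    "run_cell_timelapse",
    "admissible_range",
    "write_report",
    "default_population",
]

log = logging.getLogger("qpibench.sweeps")

SPHERE_MIN_AREA_UM2 = 100.0
CELL_MIN_AREA_UM2 = 50.0


@dataclass
class SweepResult:
    """Per-parameter-value aggregates of a sensitivity sweep.

    ``table`` has one row per parameter value; rows where reconstruction
    failed are flagged (``failed``) with NaN metrics, never dropped.
    Baseline-referenced percent errors are zero at ``baseline_index`` by
    construction.
    """

    parameter_name: str
    table: pd.DataFrame
    baseline_index: int
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def parameter_values(self) -> np.ndarray:
        return self.table["value"].to_numpy()


def default_population(n_spheres: int = 20, rng_seed: int = 0) -> list[SphereSpec]:
    """The default 20-bead population (D ~ U(63, 75) μm, Δn = 0.0187)."""
    return random_sphere_population(n_spheres=n_spheres, rng_seed=rng_seed)


def tile_sphere_fields(
    population: Sequence[SphereSpec],
    field_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    per_field: int = 4,
) -> list[list[SphereSpec]]:
    """Place beads on a grid across as many fields as needed.

    Beads are assigned positions on a per-field square grid with enough
    clearance that footprints never overlap or touch the border band.
    """
    if not population:
        raise ValueError("empty sphere population")
    ny, nx = field_shape
    side = int(np.ceil(np.sqrt(per_field)))
    w, h = nx * pixel_size, ny * pixel_size
    max_d = max(s.diameter for s in population)
    pitch_x, pitch_y = w / side, h / side
    if min(pitch_x, pitch_y) < max_d + 10 * pixel_size:
        raise ValueError(
            f"cannot tile {per_field} beads of up to {max_d:.0f} μm "
            f"into a {w:.0f}x{h:.0f} μm field"
        )
    fields: list[list[SphereSpec]] = []
    for start in range(0, len(population), per_field):
        chunk = population[start:start + per_field]
        placed = []
        for i, spec in enumerate(chunk):
            gx, gy = i % side, i // side
            placed.append(SphereSpec(
                center_x=(gx + 0.5) * pitch_x,
                center_y=(gy + 0.5) * pitch_y,
                diameter=spec.diameter,
                n_sphere=spec.n_sphere,
                n_medium=spec.n_medium,
            ))
        fields.append(placed)
    return fields


def _acquire(
    truth: PhaseImage,
    acq: AcquisitionConfig,
    det: DetectorConfig,
    rng: np.random.Generator,
    n_angles: int,
    degraded: PhaseImage | None = None,
):
    """Forward model one field: degraded OPD → sample/reference fringes.

    ``degraded`` short-circuits the (deterministic, expensive) partial
    coherence computation when the caller has cached it.
    """
    if degraded is None:
        degraded = partial_coherent_opd(truth, acq, n_angles=n_angles)
    flat = truth.with_opd(np.zeros(truth.shape))
    sample = synthesize_interferogram(degraded, det, acq, rng=rng)
    reference = synthesize_interferogram(flat, det, acq, rng=rng)
    return sample, reference


def _reconstruct_field(sample, reference, det: DetectorConfig) -> PhaseImage:
    opd_s = reconstruct_opd(sample, det)
    opd_r = reconstruct_opd(reference, det)
    recon = reference_subtract(opd_s, opd_r)
    thr = isodata_threshold(recon.opd)
    rough = ndimage.binary_dilation(recon.opd > thr, iterations=3)
    return background_offset_correct(recon, rough)


def _segment_spheres(recon: PhaseImage, contraction_bias: float, n_iter: int):
    thr = isodata_threshold(recon.opd)
    init = ndimage.binary_dilation(recon.opd > thr, iterations=3)
    seg = active_contour_segment(recon, init, contraction_bias=contraction_bias,
                                 n_iter=n_iter)
    return filter_objects(seg, min_area=SPHERE_MIN_AREA_UM2, exclude_border=True)


def measure_sphere_field(
    truth_specs: Sequence[SphereSpec],
    acq: AcquisitionConfig,
    det: DetectorConfig,
    rng: np.random.Generator,
    field_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    n_angles: int = 37,
    contraction_bias: float = -0.8,
    n_iter: int = 300,
    degraded: PhaseImage | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Simulate → reconstruct → segment → measure one bead field.

    The headline ``delta_n`` column divides the peak OPD by the diameter
    measured on the matching brightfield phantom (IsoData segmentation), the
    way the bench protocol determines D; the phase-mask equivalent diameter
    is kept as ``delta_n_phase``/``D_um``. Returns the per-object table
    (with ground-truth columns ``true_delta_n``/``true_D_um``) and
    per-field diagnostics (mean counts, saturation fraction, aliasing flag).
    """
    truth = multi_sphere_opd_map(list(truth_specs), field_shape, pixel_size,
                                 acq.wavelength)
    sample, reference = _acquire(truth, acq, det, rng, n_angles,
                                 degraded=degraded)
    info = {
        "mean_counts": float(sample.counts.mean()),
        "saturation_fraction": saturation_fraction(sample),
        "aliasing": bool(sample.metadata.get("aliasing", False)),
    }
    recon = _reconstruct_field(sample, reference, det)
    seg = _segment_spheres(recon, contraction_bias, n_iter)
    df = measure_objects(recon, seg)

    # brightfield diameters: segment the matching dark-disk phantom once
    bf = brightfield_phantom(list(truth_specs), field_shape, pixel_size)
    bf_labels, _ = ndimage.label(bf <= isodata_threshold(bf))
    bf_seg = filter_objects(
        segmentation_from_labels(bf_labels, pixel_size),
        min_area=SPHERE_MIN_AREA_UM2)

    def _nearest(cx, cy, centers, radii):
        best, best_dist = None, np.inf
        for i, (px, py) in enumerate(centers):
            dist = np.hypot(cx - px, cy - py)
            if dist < best_dist:
                best, best_dist = i, dist
        if best is not None and best_dist < radii[best]:
            return best
        return None

    truth_centers = [(s.center_x, s.center_y) for s in truth_specs]
    truth_radii = [s.radius for s in truth_specs]
    bf_centers = list(zip(bf_seg.objects.centroid_x_um,
                          bf_seg.objects.centroid_y_um))
    bf_d = bf_seg.objects.equivalent_diameter_um.to_numpy()
    bf_radii = list(bf_d / 2.0)

    true_dn, true_d, d_bf = [], [], []
    for _, row in df.iterrows():
        obj = seg.objects.loc[seg.objects.object_id == row.object_id].iloc[0]
        ti = _nearest(obj.centroid_x_um, obj.centroid_y_um,
                      truth_centers, truth_radii)
        true_dn.append(truth_specs[ti].delta_n if ti is not None else np.nan)
        true_d.append(truth_specs[ti].diameter if ti is not None else np.nan)
        bi = _nearest(obj.centroid_x_um, obj.centroid_y_um, bf_centers, bf_radii)
        d_bf.append(bf_d[bi] if bi is not None else np.nan)
    df = df.assign(true_delta_n=true_dn, true_D_um=true_d, D_bf_um=d_bf)
    df = df.rename(columns={"delta_n": "delta_n_phase"})
    df["delta_n"] = df.opd_max_nm / (1000.0 * df.D_bf_um)
    return df, info


def _aggregate_rows(
    per_value: list[tuple[float, pd.DataFrame | None, dict[str, Any]]],
    baseline_value: float,
) -> tuple[pd.DataFrame, int]:
    rows = []
    for value, df, info in per_value:
        failed = df is None or len(df) == 0
        row = {
            "value": value,
            "failed": failed,
            "n_objects": 0 if failed else len(df),
            "mean_counts": info.get("mean_counts", np.nan),
            "saturation_fraction": info.get("saturation_fraction", np.nan),
        }
        if failed:
            row.update({k: np.nan for k in
                        ("delta_n_mean", "delta_n_sem", "ov_mean", "ov_sem")})
        else:
            n = len(df)
            row["delta_n_mean"] = df.delta_n.mean()
            row["delta_n_sem"] = df.delta_n.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            row["ov_mean"] = df.ov_um3.mean()
            row["ov_sem"] = df.ov_um3.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)
    base_candidates = np.nonzero(np.isclose(table["value"], baseline_value))[0]
    if base_candidates.size == 0:
        raise ValueError(f"baseline value {baseline_value} not in sweep grid")
    b = int(base_candidates[0])
    if table.loc[b, "failed"]:
        raise ValueError("baseline condition failed to reconstruct")
    for metric in ("delta_n", "ov"):
        ref = table.loc[b, f"{metric}_mean"]
        table[f"{metric}_pct_err"] = 100.0 * (table[f"{metric}_mean"] - ref) / ref
    return table, b


def _run_sphere_sweep(
    parameter_name: str,
    conditions: list[tuple[float, AcquisitionConfig]],
    baseline_value: float,
    population: Sequence[SphereSpec],
    det: DetectorConfig,
    seed: int,
    field_shape: tuple[int, int],
    pixel_size: float,
    per_field: int,
    n_angles: int,
) -> SweepResult:
    if not population:
        raise ValueError("empty sphere population")
    fields = tile_sphere_fields(population, field_shape, pixel_size, per_field)
    pc_cache: dict[tuple, PhaseImage] = {}
    per_value = []
    for ci, (value, acq) in enumerate(conditions):
        rng = np.random.default_rng([seed, ci])
        frames, infos = [], []
        try:
            for fi, specs in enumerate(fields):
                key = (fi, round(acq.condenser_na, 9), round(acq.defocus_z, 6))
                if key not in pc_cache:
                    truth = multi_sphere_opd_map(list(specs), field_shape,
                                                 pixel_size, acq.wavelength)
                    pc_cache[key] = partial_coherent_opd(truth, acq,
                                                         n_angles=n_angles)
                df, info = measure_sphere_field(
                    specs, acq, det, rng, field_shape, pixel_size, n_angles,
                    degraded=pc_cache[key])
                frames.append(df)
                infos.append(info)
            frames = [f for f in frames if len(f)]
            merged = pd.concat(frames, ignore_index=True) if frames else None
            info = {
                "mean_counts": float(np.mean([i["mean_counts"] for i in infos])),
                "saturation_fraction": float(
                    np.mean([i["saturation_fraction"] for i in infos])),
            }
        except ValueError as exc:
            log.warning("%s=%g: reconstruction failed (%s)",
                        parameter_name, value, exc)
            merged, info = None, {}
        log.info("%s=%g: n=%s", parameter_name, value,
                 0 if merged is None else len(merged))
        per_value.append((value, merged, info))
    table, b = _aggregate_rows(per_value, baseline_value)
    detail = {v: df for v, df, _ in per_value if df is not None}
    return SweepResult(parameter_name, table, b,
                       metadata={"seed": seed, "per_value_objects": detail})


def run_na_sweep(
    population: Sequence[SphereSpec],
    na_values: Sequence[float],
    acq_base: AcquisitionConfig | None = None,
    det: DetectorConfig | None = None,
    seed: int = 0,
    field_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    per_field: int = 4,
    n_angles: int = 37,
) -> SweepResult:
    """Condenser-NA sensitivity sweep.

    At each NA the exposure is rescaled by (NA_base/NA)² so the mean image
    intensity stays at the detector target, as the bench protocol does.
    The grid must include the 0.09 baseline.
    """
    acq_base = acq_base or AcquisitionConfig()
    det = det or DetectorConfig()
    conditions = []
    for na in na_values:
        acq = acq_base.replace(
            condenser_na=float(na),
            exposure_time=acq_base.exposure_time
            * (acq_base.condenser_na / float(na)) ** 2,
        )
        conditions.append((float(na), acq))
    return _run_sphere_sweep("condenser_na", conditions, acq_base.condenser_na,
                             population, det, seed, field_shape, pixel_size,
                             per_field, n_angles)


def run_energy_sweep(
    population: Sequence[SphereSpec],
    energy_scales: Sequence[float],
    acq_base: AcquisitionConfig | None = None,
    det: DetectorConfig | None = None,
    seed: int = 0,
    field_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    per_field: int = 4,
    n_angles: int = 37,
    vary: str = "irradiance",
) -> SweepResult:
    """Illumination-energy sweep (scales relative to the baseline energy).

    ``vary`` selects which knob carries the scale: ``"irradiance"`` (constant
    exposure time, the protocol's stated mode) or ``"exposure"``. Either way
    counts scale linearly until the full well clips them. The result's table
    carries the realized energy (μJ) and the saturation fraction per value;
    count histograms are stored in ``metadata["histograms"]``.
    """
    acq_base = acq_base or AcquisitionConfig()
    det = det or DetectorConfig()
    conditions = []
    for sc in energy_scales:
        if vary == "irradiance":
            acq = acq_base.replace(irradiance=acq_base.irradiance * float(sc))
        elif vary == "exposure":
            acq = acq_base.replace(exposure_time=acq_base.exposure_time * float(sc))
        else:
            raise ValueError("vary must be 'irradiance' or 'exposure'")
        conditions.append((float(sc), acq))
    result = _run_sphere_sweep("energy_scale", conditions, 1.0, population,
                               det, seed, field_shape, pixel_size, per_field,
                               n_angles)
    energies = [illumination_energy(acq)[0] for _, acq in conditions]
    result.table["energy_uJ"] = energies
    # count histograms for the saturation analysis (Fig-3B-style)
    hists = {}
    truth = multi_sphere_opd_map(
        list(tile_sphere_fields(population, field_shape, pixel_size, per_field)[0]),
        field_shape, pixel_size, acq_base.wavelength)
    for (sc, acq) in conditions:
        rng = np.random.default_rng([seed, 9999])
        sample = synthesize_interferogram(
            partial_coherent_opd(truth, acq, n_angles=min(n_angles, 7)),
            det, acq, rng=rng)
        counts, edges = np.histogram(sample.counts, bins=64,
                                     range=(0, det.full_well_counts))
        hists[sc] = {"counts": counts.tolist(), "edges": edges.tolist()}
    result.metadata["histograms"] = hists
    return result


def run_focus_sweep(
    population: Sequence[SphereSpec],
    z_values: Sequence[float],
    acq_base: AcquisitionConfig | None = None,
    det: DetectorConfig | None = None,
    seed: int = 0,
    field_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    per_field: int = 4,
    n_angles: int = 37,
) -> SweepResult:
    """Defocus sensitivity sweep; the grid must include z = 0 (baseline)."""
    acq_base = acq_base or AcquisitionConfig()
    det = det or DetectorConfig()
    conditions = [(float(z), acq_base.replace(defocus_z=float(z)))
                  for z in z_values]
    return _run_sphere_sweep("defocus_z", conditions, 0.0, population, det,
                             seed, field_shape, pixel_size, per_field, n_angles)


def run_cell_timelapse(
    cell_params: dict[str, Any] | None,
    n_frames: int,
    acq_variants: dict[str, AcquisitionConfig],
    det: DetectorConfig | None = None,
    seed: int = 0,
    baseline: str | None = None,
    n_angles: int = 9,
    greediness: float = 0.0,
) -> SweepResult:
    """Cell-field time-lapse under acquisition variants.

    A fixed cell layout (drawn from ``seed``) is imaged ``n_frames`` times
    with small per-frame amplitude fluctuations and fresh detector noise,
    once per variant. Whole-field area, dry mass (summed OPD over the union
    mask / α) and mass density are measured per frame with the
    gradient-threshold segmenter at one fixed greediness; percent changes
    are computed per frame against the baseline variant and averaged, with
    the SEM taken across time points.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    det = det or DetectorConfig()
    params = {"n_cells": 12, "shape": (512, 512), "pixel_size": 0.65}
    params.update(cell_params or {})
    if baseline is None:
        baseline = next(iter(acq_variants))
    if baseline not in acq_variants:
        raise ValueError(f"baseline variant {baseline!r} not among variants")

    base_field = cell_field(rng_seed=seed, **params)
    jitter_rng = np.random.default_rng([seed, 1])
    amp = 1.0 + np.cumsum(jitter_rng.normal(0.002, 0.004, size=n_frames))

    per_variant_frames: dict[str, pd.DataFrame] = {}
    for vi, (name, acq) in enumerate(acq_variants.items()):
        rng = np.random.default_rng([seed, 2, vi])
        recs = []
        for f in range(n_frames):
            phase = base_field.phase.with_opd(base_field.phase.opd * amp[f])
            try:
                sample, reference = _acquire(phase, acq, det, rng, n_angles)
                recon = _reconstruct_field(sample, reference, det)
            except ValueError as exc:
                # fringe washout (e.g. heavy saturation): flag, keep the row
                log.warning("variant %s frame %d: reconstruction failed (%s)",
                            name, f, exc)
                recs.append({"frame": f, "area_um2": np.nan, "mass_pg": np.nan,
                             "density_pg_um2": np.nan, "n_objects": 0})
                continue
            seg = gradient_threshold_segment(recon, greediness=greediness,
                                             min_area=CELL_MIN_AREA_UM2)
            union = seg.mask()
            if union.any():
                area = float(union.sum()) * recon.pixel_size**2
                ov = optical_volume(recon, union)
            else:
                area, ov = 0.0, 0.0
            mass = ov / 0.18
            recs.append({
                "frame": f,
                "area_um2": area,
                "mass_pg": mass,
                "density_pg_um2": mass / area if area > 0 else np.nan,
                "n_objects": seg.n_objects,
            })
        frames = pd.DataFrame(recs)
        if name == baseline and not (frames["area_um2"] > 0).any():
            raise ValueError("baseline variant: all frames segmented empty")
        per_variant_frames[name] = frames
        log.info("variant %s: mean area %.0f μm², mean mass %.0f pg", name,
                 frames.area_um2.mean(), frames.mass_pg.mean())

    base_frames = per_variant_frames[baseline]
    rows = []
    names = list(acq_variants)
    for name in names:
        fdf = per_variant_frames[name]
        row: dict[str, Any] = {"value": name,
                               "failed": bool(fdf.area_um2.isna().all()),
                               "n_objects": int(fdf.n_objects.mean())}
        for metric, col in (("area", "area_um2"), ("mass", "mass_pg"),
                            ("density", "density_pg_um2")):
            pct = 100.0 * (fdf[col] - base_frames[col]) / base_frames[col]
            row[f"{metric}_mean"] = fdf[col].mean()
            row[f"{metric}_pct_change"] = pct.mean()
            row[f"{metric}_pct_sem"] = (pct.std(ddof=1) / np.sqrt(len(pct))
                                        if len(pct) > 1 else 0.0)
        rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(
        "variant", table, names.index(baseline),
        metadata={"seed": seed, "frames": per_variant_frames,
                  "ground_truth_ov_um3": base_field.optical_volume},
    )


def admissible_range(
    sweep: SweepResult,
    metric: str,
    tolerance_pct: float,
) -> tuple[float, float]:
    """Largest contiguous parameter interval around the baseline where
    |metric| ≤ tolerance (endpoints at grid resolution).

    ``metric`` names a percent-error column of the sweep table (e.g.
    ``"ov_pct_err"``). Failed rows count as out of tolerance. Raises if the
    sweep has fewer than 3 values or the baseline itself fails the tolerance.
    """
    table = sweep.table
    if len(table) < 3:
        raise ValueError("sweep needs at least 3 parameter values")
    order = np.argsort(table["value"].to_numpy())
    values = table["value"].to_numpy()[order]
    errs = np.abs(table[metric].to_numpy()[order])
    failed = table["failed"].to_numpy()[order]
    ok = (~failed) & (np.nan_to_num(errs, nan=np.inf) <= tolerance_pct)
    b = int(np.nonzero(order == sweep.baseline_index)[0][0])
    if not ok[b]:
        raise ValueError("baseline fails tolerance")
    lo = b
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = b
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return float(values[lo]), float(values[hi])


def write_report(
    sweeps: dict[str, SweepResult],
    out_dir: str | Path,
    tolerance_pct: float = 5.0,
    plots: bool = False,
) -> list[Path]:
    """Write one CSV per sweep plus a JSON summary of admissible ranges."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    summary: dict[str, Any] = {}
    for name, sweep in sweeps.items():
        csv_path = out_dir / f"sweep_{name}.csv"
        sweep.table.to_csv(csv_path, index=False, float_format="%.10g")
        written.append(csv_path)
        ranges = {}
        for metric in sweep.table.columns:
            if not metric.endswith(("_pct_err", "_pct_change")):
                continue
            try:
                ranges[metric] = admissible_range(sweep, metric, tolerance_pct)
            except ValueError:
                ranges[metric] = None
        summary[name] = {
            "parameter": sweep.parameter_name,
            "tolerance_pct": tolerance_pct,
            "admissible": ranges,
        }
        if plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots()
            for metric in ("delta_n_pct_err", "ov_pct_err"):
                if metric in sweep.table:
                    ax.plot(sweep.table["value"], sweep.table[metric].abs(),
                            marker="o", label=metric)
            ax.set_xlabel(sweep.parameter_name)
            ax.set_ylabel("|percent error|")
            ax.legend()
            png = out_dir / f"sweep_{name}.png"
            fig.savefig(png, dpi=110)
            plt.close(fig)
            written.append(png)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written.append(summary_path)
    return written
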