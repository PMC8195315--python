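"""Thresholding and contour segmentation against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from qpibench import (
    PhaseImage,
    SphereSpec,
    active_contour_segment,
    brightfield_phantom,
    cell_field,
    filter_objects,
    gradient_threshold_segment,
    isodata_threshold,
    segmentation_from_labels,
    sphere_opd_map,
)

PIXEL = 0.65


def brute_force_intermeans(image, n_bins=256):
    """Oracle: exhaustive scan for the intermeans fixed point over all bins."""
    lo, hi = float(image.min()), float(image.max())
    hist, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = np.nonzero(hist)[0]
    solutions = []
    for k in range(occupied[0], occupied[-1]):
        below = np.arange(n_bins) <= k
        w_lo, w_hi = hist[below].sum(), hist[~below].sum()
        if w_lo == 0 or w_hi == 0:
            continue
        t = 0.5 * ((hist[below] * centers[below]).sum() / w_lo
                   + (hist[~below] * centers[~below]).sum() / w_hi)
        k_implied = int(np.clip(np.searchsorted(centers, t, side="right") - 1,
                                occupied[0], occupied[-1] - 1))
        if k_implied == k:
            solutions.append(t)
    return solutions


class TestIsodata:
    def test_two_delta_masses_split_at_midpoint(self):
        image = np.array([10.0] * 50 + [200.0] * 50)
        assert isodata_threshold(image) == pytest.approx(105.0, abs=0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        image = np.concatenate([rng.normal(40, 12, 600),
                                rng.normal(160, 25, 400)])
        t = isodata_threshold(image)
        solutions = brute_force_intermeans(image)
        assert solutions, "oracle found no fixed point"
        assert min(abs(t - s) for s in solutions) < 1e-9

    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0),
           seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_equivariance(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        image = np.concatenate([rng.normal(30, 8, 300),
                                rng.normal(120, 15, 300)])
        t = isodata_threshold(image)
        t_affine = isodata_threshold(scale * image + offset)
        assert t_affine == pytest.approx(scale * t + offset,
                                         rel=1e-9, abs=1e-6 * scale)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            isodata_threshold(np.full((32, 32), 5.0))

    def test_brightfield_bead_diameter_within_2_percent(self):
        spec = SphereSpec(83.2, 83.2, 67.7, 1.488, 1.468)
        bf = brightfield_phantom(spec, (256, 256), PIXEL)
        labels, _ = ndimage.label(bf <= isodata_threshold(bf))
        seg = segmentation_from_labels(labels, PIXEL)
        d = seg.objects.equivalent_diameter_um.iloc[0]
        assert d == pytest.approx(67.7, rel=0.02)


class TestActiveContour:
    def test_perfect_binary_phantom_is_fixed_point(self):
        truth = np.zeros((128, 128), bool)
        truth[40:90, 30:80] = True
        image = PhaseImage(np.where(truth, 800.0, 0.0), PIXEL)
        seg = active_contour_segment(image, truth)
        mask = seg.mask()
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard == 1.0

    def test_dilated_init_converges_to_bead_edge(self, centered_sphere_phase):
        truth = centered_sphere_phase.opd > 0
        init = ndimage.binary_dilation(truth, iterations=8)
        seg = active_contour_segment(centered_sphere_phase, init)
        mask = seg.mask()
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.95

    def test_flat_image_collapses_with_named_settings(self):
        flat = PhaseImage(np.zeros((64, 64)), PIXEL)
        init = np.zeros((64, 64), bool)
        init[20:40, 20:40] = True
        with pytest.raises(ValueError, match="contraction_bias"):
            active_contour_segment(flat, init, contraction_bias=-5.0)

    def test_empty_init_rejected(self, centered_sphere_phase):
        with pytest.raises(ValueError, match="empty"):
            active_contour_segment(centered_sphere_phase,
                                   np.zeros((256, 256), bool))

    def test_deterministic(self, centered_sphere_phase):
        init = ndimage.binary_dilation(centered_sphere_phase.opd > 100,
                                       iterations=5)
        a = active_contour_segment(centered_sphere_phase, init)
        b = active_contour_segment(centered_sphere_phase, init)
        assert np.array_equal(a.label_image, b.label_image)


class TestGradientThreshold:
    def test_flat_image_yields_empty_segmentation(self):
        seg = gradient_threshold_segment(PhaseImage(np.zeros((128, 128)), PIXEL))
        assert seg.n_objects == 0

    def test_recovers_all_cells_with_good_overlap(self):
        field = cell_field(5, rng_seed=2)
        seg = gradient_threshold_segment(field.phase)
        assert seg.n_objects == 5
        for i in range(1, 6):
            truth = field.labels == i
            best = max(
                ((seg.mask(int(oid)) & truth).sum()
                 / (seg.mask(int(oid)) | truth).sum())
                for oid in seg.objects.object_id)
            assert best >= 0.8

    def test_amplitude_rescaling_changes_segmented_area(self):
        # the threshold is not exactly scale invariant (absolute noise
        # floor), so inflating the OPD amplitude shifts the boundary
        field = cell_field(5, rng_seed=2)
        a1 = gradient_threshold_segment(field.phase).objects.area_um2.sum()
        a3 = gradient_threshold_segment(
            field.phase.with_opd(field.phase.opd * 3.0)).objects.area_um2.sum()
        assert a1 > 0 and a3 != a1

    def test_greediness_admits_more_area(self):
        field = cell_field(5, rng_seed=2)
        tight = gradient_threshold_segment(field.phase, greediness=-0.5)
        greedy = gradient_threshold_segment(field.phase, greediness=0.5)
        assert greedy.mask().sum() > tight.mask().sum()


class TestFilterObjects:
    def _random_labels(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros((96, 96), np.int32)
        for i in range(1, 9):
            cy, cx = rng.integers(5, 91, 2)
            r = int(rng.integers(2, 9))
            yy, xx = np.ogrid[:96, :96]
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = i
        return labels

    def test_no_op_filter_is_identity(self):
        seg = segmentation_from_labels(self._random_labels(0), PIXEL)
        out = filter_objects(seg, min_area=0.0, exclude_border=False)
        assert out.n_objects == seg.n_objects
        assert np.array_equal(out.mask(), seg.mask())

    def test_border_clipped_object_removed(self):
        labels = np.zeros((64, 64), np.int32)
        labels[0:10, 20:30] = 1       # touches the border
        labels[30:40, 30:40] = 2
        seg = segmentation_from_labels(labels, PIXEL)
        out = filter_objects(seg, exclude_border=True)
        assert out.n_objects == 1
        assert not out.objects.touches_border.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_survivor_count_matches_enumeration(self, seed):
        seg = segmentation_from_labels(self._random_labels(seed), PIXEL)
        min_area = 60.0
        out = filter_objects(seg, min_area=min_area, exclude_border=True)
        expected = sum(
            1 for _, row in seg.objects.iterrows()
            if row.area_um2 >= min_area and not row.touches_border)
        assert out.n_objects == expected
        # labels stay contiguous 1..n
        present = np.unique(out.label_image)
        assert list(present[present > 0]) == list(range(1, out.n_objects + 1))
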