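"""Projection quantification: enhancement, segmentation, maps, classes."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from trichrome import phantom
from trichrome.core import InvalidParameterError
from trichrome.projection import (
    CLASS_ORDER,
    EMPTY_CLASS,
    REFERENCE_POINTS,
    SignalMask,
    classify_superpixels,
    confidence_map,
    enhance_channel,
    exclusive_masks,
    histogram_from_plane,
    multiotsu_thresholds,
    quantify_projections,
    region_proportions,
    segment_channel,
    strength_map,
)


def brute_force_multiotsu(counts, centers, n_classes):
    """Exhaustive maximiser of between-class variance over bin cut points."""
    counts = np.asarray(counts, float)
    centers = np.asarray(centers, float)
    total = counts.sum()
    best, best_cuts = -np.inf, None
    nbins = len(counts)
    for cuts in itertools.combinations(range(1, nbins), n_classes - 1):
        edges = (0,) + cuts + (nbins,)
        var = 0.0
        ok = True
        for lo, hi in zip(edges[:-1], edges[1:]):
            w = counts[lo:hi].sum()
            if w == 0:
                ok = False
                break
            mu = (counts[lo:hi] * centers[lo:hi]).sum() / w
            var += w / total * mu**2
        if ok and var > best:
            best, best_cuts = var, cuts
    return best, best_cuts


def _partition_variance(counts, centers, cuts):
    total = counts.sum()
    edges = (0,) + tuple(sorted(cuts)) + (len(counts),)
    var = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = counts[lo:hi].sum()
        if w == 0:
            continue
        mu = (counts[lo:hi] * centers[lo:hi]).sum() / w
        var += w / total * mu**2
    return var


def _criterion_value(counts, centers, thresholds):
    """Between-class variance achieved by threshold values.

    A returned threshold names a bin centre, but whether that bin closes
    the lower class or opens the upper one is a convention, so the best
    of the two adjacent cut positions is scored per threshold.
    """
    counts = np.asarray(counts, float)
    centers = np.asarray(centers, float)
    idx = [int(np.argmin(np.abs(centers - t))) for t in thresholds]
    best = -np.inf
    for sides in itertools.product((0, 1), repeat=len(idx)):
        cuts = tuple(i + s for i, s in zip(idx, sides))
        if len(set(cuts)) != len(cuts) or any(not 1 <= c <= len(counts) - 1 for c in cuts):
            continue
        best = max(best, _partition_variance(counts, centers, cuts))
    return best


class TestEnhance:
    def test_matching_to_own_histogram_is_near_identity(self, rng):
        plane = rng.gamma(2.0, 10.0, size=(64, 64))
        ref = histogram_from_plane(np.sqrt(plane), nbins=1024)
        out = enhance_channel(plane, ref)
        # quantised through 1024 bins: equal up to one bin width
        bin_w = np.ptp(np.sqrt(plane)) / 1024
        assert np.abs(out - np.sqrt(plane)).max() < 2 * bin_w

    def test_zero_maps_to_the_histogram_floor(self):
        ref = histogram_from_plane(np.array([0.0, 1.0, 2.0, 3.0]), nbins=4)
        out = enhance_channel(np.zeros((4, 4)), ref)
        assert np.unique(out).size == 1

    def test_rank_order_is_preserved(self, rng):
        plane = rng.permutation(400).astype(float).reshape(20, 20)
        ref = histogram_from_plane(rng.gamma(3.0, 5.0, 4000), nbins=256)
        out = enhance_channel(plane, ref)
        rho = spearmanr(plane.ravel(), out.ravel()).statistic
        assert rho == pytest.approx(1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            enhance_channel(np.array([[-1.0]]))


class TestSegmentation:
    def test_two_level_plane_segments_exactly(self, rng):
        truth = rng.random((60, 60)) > 0.7
        plane = np.where(truth, 200.0, 10.0)
        mask = segment_channel(plane, n_classes=2, min_component_px=1)
        np.testing.assert_array_equal(mask.mask, truth)

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_thresholds_maximise_between_class_variance(self, rng, n_classes):
        counts = rng.integers(0, 50, size=64).astype(float)
        counts[counts.argmin()] += 1  # avoid an all-zero histogram
        centers = np.linspace(0.5, 63.5, 64)
        thr = multiotsu_thresholds(counts, centers, n_classes)
        best, _ = brute_force_multiotsu(counts, centers, n_classes)
        achieved = _criterion_value(counts, centers, thr)
        assert achieved == pytest.approx(best, rel=1e-12)

    def test_small_components_are_removed_by_size(self):
        plane = np.zeros((20, 20))
        plane[1, 1:5] = 100.0  # 4-pixel blob
        plane[10, 1:6] = 100.0  # 5-pixel blob
        mask = segment_channel(plane, n_classes=2, min_component_px=5)
        assert not mask.mask[1, 1:5].any()
        assert mask.mask[10, 1:6].all()

    def test_degenerate_histogram_raises(self):
        with pytest.raises(InvalidParameterError):
            segment_channel(np.full((8, 8), 3.0), n_classes=2)


class TestExclusiveMasks:
    def _masks(self, *arrays):
        return [SignalMask(a, c) for a, c in zip(arrays, "RGB")]

    def test_disjoint_inputs_pass_through(self, rng):
        r = np.zeros((10, 10), bool); r[:3] = True
        g = np.zeros((10, 10), bool); g[5:7] = True
        b = np.zeros((10, 10), bool); b[9:] = True
        out = exclusive_masks(self._masks(r, g, b))
        for before, after in zip([r, g, b], out):
            np.testing.assert_array_equal(after.mask, before)

    def test_identical_inputs_vanish(self):
        m = np.ones((5, 5), bool)
        out = exclusive_masks(self._masks(m, m.copy(), m.copy()))
        assert not any(o.mask.any() for o in out)

    def test_shared_pixel_removed_only_from_sharing_channels(self):
        r = np.zeros((4, 4), bool); g = np.zeros((4, 4), bool); b = np.zeros((4, 4), bool)
        r[2, 2] = g[2, 2] = True
        b[0, 0] = True
        out = exclusive_masks(self._masks(r, g, b))
        assert not out[0].mask[2, 2] and not out[1].mask[2, 2]
        assert out[2].mask[0, 0]

    def test_outputs_pairwise_disjoint_on_random_masks(self, rng):
        masks = self._masks(*(rng.random((30, 30)) > 0.5 for _ in range(3)))
        out = exclusive_masks(masks)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (out[i].mask & out[j].mask).any()


class TestStrengthAndConfidence:
    def test_empty_and_full_masks(self):
        empty = strength_map(SignalMask(np.zeros((60, 60), bool)), 30)
        full = strength_map(SignalMask(np.ones((60, 60), bool)), 30)
        assert not empty.values.any()
        np.testing.assert_allclose(full.values, 1.0)

    def test_direct_count_example(self, rng):
        mask = np.zeros((30, 30), bool)
        chosen = rng.choice(900, size=90, replace=False)
        mask.ravel()[chosen] = True
        sm = strength_map(SignalMask(mask), 30)
        assert sm.values[0, 0] == pytest.approx(0.1)

    def test_edge_blocks_use_their_actual_area(self):
        mask = np.ones((45, 30), bool)  # bottom blocks are 15 px tall
        sm = strength_map(SignalMask(mask), 30)
        np.testing.assert_allclose(sm.values, 1.0)

    def test_strength_is_monotone_in_the_mask(self, rng):
        base = rng.random((90, 90)) > 0.8
        grown = base | (rng.random((90, 90)) > 0.9)
        a = strength_map(SignalMask(base), 30).values
        b = strength_map(SignalMask(grown), 30).values
        assert (b >= a).all()

    def test_confidence_is_one_without_overlap_and_half_with(self):
        total = np.zeros((30, 30), bool)
        total[0, :10] = True
        excl_full = SignalMask(total.copy())
        cm = confidence_map(excl_full, SignalMask(total), 30)
        assert cm.values[0, 0] == 1.0
        half = total.copy()
        half[0, 5:10] = False
        cm2 = confidence_map(SignalMask(half), SignalMask(total), 30)
        assert cm2.values[0, 0] == pytest.approx(0.5)

    def test_no_signal_block_is_flagged_not_zero(self):
        z = SignalMask(np.zeros((30, 30), bool))
        cm = confidence_map(z, z, 30)
        assert np.isnan(cm.values[0, 0])

    def test_exclusive_outside_total_rejected(self):
        excl = SignalMask(np.ones((6, 6), bool))
        total = SignalMask(np.zeros((6, 6), bool))
        with pytest.raises(InvalidParameterError):
            confidence_map(excl, total, 3)


class TestClassification:
    def test_each_reference_point_is_its_own_class(self):
        stack = REFERENCE_POINTS.T.reshape(3, -1, 1)
        codes = classify_superpixels(stack).ravel()
        np.testing.assert_array_equal(codes, np.arange(7))

    def test_dual_example_by_explicit_distance_check(self):
        contrib = np.array([0.45, 0.45, 0.10])
        d = np.linalg.norm(REFERENCE_POINTS - contrib, axis=1)
        assert CLASS_ORDER[d.argmin()] == "RG"
        code = classify_superpixels(contrib.reshape(3, 1, 1))[0, 0]
        assert CLASS_ORDER[code] == "RG"

    def test_equal_contributions_classify_as_triple(self):
        code = classify_superpixels(np.full((3, 1, 1), 1 / 3))[0, 0]
        assert CLASS_ORDER[code] == "RGB"

    def test_zero_strength_superpixel_is_empty(self):
        assert classify_superpixels(np.zeros((3, 2, 2)))[0, 0] == EMPTY_CLASS

    def test_classification_invariant_to_overall_gain(self, rng):
        stack = rng.random((3, 8, 8))
        np.testing.assert_array_equal(
            classify_superpixels(stack), classify_superpixels(4.2 * stack)
        )


class TestRegionProportions:
    def test_uniform_class_r(self):
        classes = np.zeros((4, 4), dtype=int)  # all class R
        props = region_proportions(classes)
        assert props["R"] == 1.0 and props.drop("R").sum() == 0.0

    def test_proportions_sum_to_one(self, rng):
        classes = rng.integers(-1, 7, size=(10, 10))
        classes[0, 0] = 0  # ensure at least one non-empty
        assert region_proportions(classes).sum() == pytest.approx(1.0)

    def test_empty_region_raises(self):
        with pytest.raises(InvalidParameterError):
            region_proportions(np.zeros((3, 3), int), np.zeros((3, 3), bool))


class TestEndToEndClosure:
    def test_disjoint_noiseless_phantom_class_map_is_exact(self, small_projection_phantom):
        image, truth = small_projection_phantom
        result = quantify_projections(image, block_px=30, n_classes=2, min_component_px=1)
        expected = classify_superpixels(truth.true_superpixel_composition)
        np.testing.assert_array_equal(result.interdigitation.classes, expected)

    def test_exclusive_strengths_sum_below_one(self, overlap_projection_phantom):
        image, _ = overlap_projection_phantom
        result = quantify_projections(image, block_px=30, n_classes=2, min_component_px=1)
        total = result.interdigitation.strengths.sum(axis=0)
        assert (total <= 1.0 + 1e-12).all()

    def test_confidence_one_where_channels_never_overlap(self, small_projection_phantom):
        image, _ = small_projection_phantom
        result = quantify_projections(image, block_px=30, n_classes=2, min_component_px=1)
        for cm in result.confidences:
            vals = cm.values[~np.isnan(cm.values)]
            np.testing.assert_allclose(vals, 1.0)

    def test_rendering_does_not_alter_stored_strengths(self, small_projection_phantom):
        image, _ = small_projection_phantom
        inter = quantify_projections(image, block_px=30, n_classes=2,
                                     min_component_px=1).interdigitation
        before = inter.strengths.copy()
        inter.render(gain=(3.0, 1.0, 0.5))
        np.testing.assert_array_equal(inter.strengths, before)
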