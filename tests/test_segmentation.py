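"""Active-contour segmentation and the entropy-difference stopping rule."""

import numpy as np
import pytest

from larynxcad import phantom, segmentation
from larynxcad.config import ScreeningThresholds, SnakeParams
from larynxcad.errors import DegenerateContourError, DegenerateInputError, NoCandidateError


class TestRegionEntropy:
    def test_constant_region_has_zero_entropy(self):
        img = np.full((10, 10), 80, dtype=np.uint8)
        assert segmentation.region_entropy(img, np.ones((10, 10), bool)) == 0.0

    def test_uniform_over_all_levels_is_eight_bits(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert segmentation.region_entropy(img, np.ones((16, 16), bool)) == pytest.approx(8.0)

    def test_two_equal_levels_is_one_bit(self):
        img = np.array([[10, 200]] * 8, dtype=np.uint8)
        assert segmentation.region_entropy(img, np.ones((8, 2), bool)) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            segmentation.region_entropy(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestSelectIteration:
    def test_minimum_at_23rd_candidate_selects_35(self):
        """Growth saturating between the 35th and 36th sweep -> 35 iterations."""
        diffs = np.full(29, 0.05)
        diffs[22] = 0.0003  # 23rd candidate (1-based)
        assert segmentation.select_iteration(diffs) == 35

    def test_strictly_increasing_differences_select_lower_bound(self):
        diffs = np.linspace(0.001, 0.1, 29)
        assert segmentation.select_iteration(diffs) == 13

    def test_ties_break_toward_smaller_iteration(self):
        diffs = np.zeros(29)
        assert segmentation.select_iteration(diffs) == 13

    def test_magnitude_is_compared_not_sign(self):
        diffs = np.full(29, -0.5)
        diffs[10] = 0.0001  # small positive beats large negatives
        assert segmentation.select_iteration(diffs) == 23


class TestAcmEvolve:
    def test_zero_iterations_returns_init(self):
        init = np.array([[10.0, 10.0], [10.0, 30.0], [30.0, 30.0], [30.0, 10.0]])
        out, energies = segmentation.acm_evolve(np.zeros((50, 50)), init, n_iter=0)
        np.testing.assert_allclose(out, init)
        assert energies == []

    def test_contour_at_external_minimum_stays_put(self):
        """With zero internal weights a contour sitting in the external
        energy's minimum basin has nothing to gain from any move."""
        init = np.array([[10.0, 10.0], [10.0, 30.0], [30.0, 30.0], [30.0, 10.0]])
        external = np.zeros((50, 50))
        for r, c in init.astype(int):
            external[r, c] = -5.0
        params = SnakeParams(w_continuity=0.0, w_curvature=0.0)
        out, _ = segmentation.acm_evolve(np.zeros((50, 50)), init, params, 5, external=external)
        np.testing.assert_allclose(out, init)

    def test_circle_converges_to_dark_disk_boundary(self):
        h = w = 120
        yy, xx = np.mgrid[0:h, 0:w]
        disk_r = 30.0
        img = np.where(np.hypot(yy - 60, xx - 60) < disk_r, 40.0, 200.0)
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        init = np.stack([60 + 34 * np.sin(theta), 60 + 34 * np.cos(theta)], axis=1)
        out, energies = segmentation.acm_evolve(img, init, SnakeParams(), 50)
        radii = np.hypot(out[:, 0] - 60, out[:, 1] - 60)
        assert np.all(np.abs(radii - disk_r) <= 2.0)
        # greedy sweeps never increase the total energy
        assert all(end <= start + 1e-9 for start, end in energies)

    def test_degenerate_init_rejected(self):
        init = np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        with pytest.raises(DegenerateContourError):
            segmentation.acm_evolve(np.zeros((20, 20)), init, n_iter=1)


class TestSegmentGlottis:
    def test_noiseless_phantom_matches_ground_truth_boundary_band(self, analyzed_noiseless):
        """The recovered mask may differ from the true triangle only within
        a one-pixel band around the true boundary (plus smoothing slack)."""
        img, gt, result = analyzed_noiseless
        seg_mask = result["segmentation"].glottis_mask
        diff = seg_mask ^ gt.glottis_mask
        from scipy import ndimage

        band = ndimage.binary_dilation(gt.glottis_mask, iterations=2) & ~ndimage.binary_erosion(
            gt.glottis_mask, iterations=2
        )
        assert (diff & ~band).sum() == 0
        assert segmentation.relative_error(seg_mask.sum(), gt.glottis_mask.sum()) < 5.0

    def test_image_without_dark_triangle_raises(self):
        img = np.full((288, 352), 180, dtype=np.uint8)
        img[::7] = 181
        with pytest.raises((NoCandidateError, DegenerateInputError)):
            segmentation.segment_glottis(img)

    def test_largest_candidate_wins(self):
        img = np.full((288, 352), 200, dtype=np.uint8)
        img[60:110, 60:90] = 30  # 50x30 = 1500 px
        img[150:230, 200:240] = 30  # 80x40 = 3200 px
        mask = segmentation.segment_glottis(img, ScreeningThresholds())
        assert mask.sum() == 3200
        assert mask[200, 220] and not mask[80, 70]


class TestCordSeeds:
    def test_symmetric_triangle_gives_mirror_symmetric_seeds(self):
        mask = np.zeros((100, 101), dtype=bool)
        for r in range(20, 80):
            half = int(round(30 * (80 - r) / 60))
            if half > 0:
                mask[r, 50 - half : 50 + half + 1] = True
        seeds = segmentation.extract_cord_seeds(mask)
        np.testing.assert_array_equal(seeds.left_mask, seeds.right_mask[:, ::-1])

    def test_seeds_disjoint_and_outside_glottis(self, analyzed_noiseless):
        img, gt, result = analyzed_noiseless
        seeds = segmentation.extract_cord_seeds(result["segmentation"].glottis_mask)
        assert not (seeds.left_mask & seeds.right_mask).any()
        assert not (seeds.left_mask & seeds.glottis_mask).any()
        assert not (seeds.right_mask & seeds.glottis_mask).any()

    def test_seeds_lie_inside_ground_truth_cords(self, analyzed_noiseless):
        img, gt, result = analyzed_noiseless
        seeds = segmentation.extract_cord_seeds(result["segmentation"].glottis_mask)
        for seed, cord in [(seeds.left_mask, gt.left_cord_mask), (seeds.right_mask, gt.right_cord_mask)]:
            inside = (seed & cord).sum() / seed.sum()
            assert inside >= 0.9  # rasterised band corners may poke out slightly

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            segmentation.extract_cord_seeds(np.zeros((50, 50), bool))


class TestSegmentCords:
    def test_iteration_counts_within_bounds(self, analyzed_noiseless):
        seg = analyzed_noiseless[2]["segmentation"]
        assert 13 <= seg.left_iters <= 41
        assert 13 <= seg.right_iters <= 41

    def test_symmetric_phantom_iteration_counts_agree(self, analyzed_noiseless):
        seg = analyzed_noiseless[2]["segmentation"]
        # vertex-phase discretisation can shift the counts by a sweep or two
        assert abs(seg.left_iters - seg.right_iters) <= 2

    def test_cord_masks_disjoint_from_glottis(self, analyzed_noiseless):
        seg = analyzed_noiseless[2]["segmentation"]
        assert not (seg.left_mask & seg.glottis_mask).any()
        assert not (seg.right_mask & seg.glottis_mask).any()

    def test_noiseless_cord_area_relative_error_small(self, analyzed_noiseless):
        img, gt, result = analyzed_noiseless
        seg = result["segmentation"]
        err_l = segmentation.relative_error(seg.left_mask.sum(), gt.left_cord_mask.sum())
        err_r = segmentation.relative_error(seg.right_mask.sum(), gt.right_cord_mask.sum())
        assert err_l <= 10.0 and err_r <= 10.0

    def test_entropy_trace_shape_and_selection(self, analyzed_noiseless):
        seg = analyzed_noiseless[2]["segmentation"]
        for trace, n in [(seg.left_trace, seg.left_iters), (seg.right_trace, seg.right_iters)]:
            assert trace.entropies.size == trace.iter_max - trace.iter_min + 2
            assert trace.differences.size == trace.iter_max - trace.iter_min + 1
            assert trace.n_star == n == trace.iter_min - 1 + trace.k_star
            k = int(np.argmin(np.abs(trace.differences)))
            assert trace.k_star == k + 1


class TestRelativeError:
    @pytest.mark.parametrize(
        "auto, ref, expected",
        [(100, 100, 0.0), (105, 100, 5.0), (0, 100, 100.0), (95, 100, 5.0)],
    )
    def test_arithmetic(self, auto, ref, expected):
        assert segmentation.relative_error(auto, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            segmentation.relative_error(10, 0)
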