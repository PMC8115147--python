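"""Geometric protrusion and gray-statistics features."""

import numpy as np
import pytest

from larynxcad import features, phantom
from larynxcad.config import FeatureConfig
from larynxcad.errors import DegenerateInputError
from larynxcad.segmentation import SegmentationResult, EntropyTrace


def _fake_segmentation(gt):
    """Wrap ground-truth masks as a segmentation result (oracle path)."""
    return SegmentationResult(
        glottis_mask=gt.glottis_mask,
        left_contour=np.zeros((4, 2)),
        right_contour=np.zeros((4, 2)),
        left_mask=gt.left_cord_mask,
        right_mask=gt.right_cord_mask,
        left_iters=13,
        right_iters=13,
        left_trace=EntropyTrace(),
        right_trace=EntropyTrace(),
    )


class TestProtrusionGeometry:
    def test_straight_edge_gives_zeros(self):
        edge = np.array([(r, 50.0) for r in range(100)])
        baseline = features.fit_cord_baseline(edge)
        assert features.protrusion_geometry(edge, baseline, "left") == (0.0, 0.0, 0.0, 0.0)

    def test_baseline_endpoints_lie_on_the_edge(self):
        edge = np.array([(r, 50.0 + 0.1 * r) for r in range(80)])
        p0, p1 = features.fit_cord_baseline(edge)
        np.testing.assert_allclose(p0, edge[0])
        np.testing.assert_allclose(p1, edge[-1])

    def test_semicircular_bump_oracle(self):
        """Semicircle of radius r on a straight edge: max deviation r,
        width 2r, length-to-width ratio 1/2.  Oracle: brute-force
        point-to-line distances on the rasterised bump."""
        r = 10.0
        rows = np.arange(200, dtype=float)
        cols = np.full(200, 50.0)
        in_bump = np.abs(rows - 100) < r
        cols[in_bump] = 50.0 + np.sqrt(r**2 - (rows[in_bump] - 100) ** 2)
        edge = np.stack([rows, cols], axis=1)
        # oracle: distances from the chord joining the end points
        p0, p1 = edge[0], edge[-1]
        d = (p1 - p0) / np.linalg.norm(p1 - p0)
        normal = np.array([-d[1], d[0]])
        brute_max = np.abs((edge - p0) @ normal).max()

        baseline = features.fit_cord_baseline(edge)
        max_dev, length, width, lw = features.protrusion_geometry(edge, baseline, "left")
        assert max_dev == pytest.approx(brute_max, abs=1e-9)
        assert max_dev == pytest.approx(r, abs=0.5)
        assert width == pytest.approx(2 * r, abs=2.0)
        assert lw == pytest.approx(0.5, abs=0.06)

    def test_deviation_below_threshold_not_abnormal(self):
        mask = np.zeros((100, 80), dtype=bool)
        mask[:, :51] = True
        mask[50, 51] = True  # 1 px blip, below the 3 px (scaled) threshold
        cf = features.extract_cord(np.full((100, 80), 100.0), mask, "left", FeatureConfig())
        assert not cf.geometric_abnormal
        assert cf.lw_ratio == 0.0


class TestCordGrayStd:
    def test_constant_cord_is_zero(self):
        img = np.full((10, 10), 99, dtype=np.uint8)
        assert features.cord_gray_std(img, np.ones((10, 10), bool)) == 0.0

    def test_two_level_half_split_is_25(self):
        img = np.concatenate([np.full(50, 100), np.full(50, 150)]).reshape(10, 10)
        assert features.cord_gray_std(img, np.ones((10, 10), bool)) == pytest.approx(25.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            features.cord_gray_std(np.zeros((5, 5)), np.zeros((5, 5), bool))

    def test_invariant_under_brightness_shift(self, rng):
        img = rng.integers(60, 180, size=(30, 30)).astype(float)
        mask = rng.random((30, 30)) > 0.4
        assert features.cord_gray_std(img + 17.3, mask) == pytest.approx(
            features.cord_gray_std(img, mask)
        )

    def test_leukoplakia_raises_std_over_matched_healthy_phantom(self):
        base = dict(noise_sigma=0.0, blur_sigma=0.0, seed=5)
        healthy, gt_h = phantom.generate_image(phantom.PhantomSpec(**base))
        sick, gt_s = phantom.generate_image(
            phantom.PhantomSpec(
                lesion=phantom.LesionSpec(label="leukoplakia", side="left", patch_intensity=235.0),
                **base,
            )
        )
        assert features.cord_gray_std(sick, gt_s.left_cord_mask) > features.cord_gray_std(
            healthy, gt_h.left_cord_mask
        )


class TestExtractFeatures:
    def test_healthy_noiseless_phantom_is_geometrically_normal(self, analyzed_noiseless):
        fv = analyzed_noiseless[2]["features"]
        assert not fv.left.geometric_abnormal
        assert not fv.right.geometric_abnormal
        assert fv.left.gray_std < 12.0 and fv.right.gray_std < 12.0

    def test_polyp_phantom_abnormal_on_lesion_side_only(self, analyzed_polyp):
        img, gt, result = analyzed_polyp
        fv = result["features"]
        assert fv.left.geometric_abnormal
        assert not fv.right.geometric_abnormal
        assert fv.left.max_deviation == pytest.approx(12.0, abs=3.0)

    def test_deterministic(self, noiseless_phantom, run_config):
        from larynxcad import pipeline

        img, _ = noiseless_phantom
        fv1 = pipeline.analyze_image(img, run_config)["features"]
        fv2 = pipeline.analyze_image(img, run_config)["features"]
        assert fv1 == fv2

    def test_bump_radius_monotonically_increases_deviation(self):
        devs = []
        for radius in (5.0, 9.0, 13.0):
            spec = phantom.PhantomSpec(
                noise_sigma=0.0,
                blur_sigma=0.0,
                lesion=phantom.LesionSpec(
                    label="polyp", side="right", protrusion_radius=radius, base_width=16.0
                ),
            )
            img, gt = phantom.generate_image(spec)
            fv = features.extract_features(img, _fake_segmentation(gt))
            devs.append(fv.right.max_deviation)
        assert devs[0] < devs[1] < devs[2]

    def test_translation_and_rotation_equivariance(self, noiseless_phantom):
        img, gt = noiseless_phantom
        fv = features.extract_features(img.astype(float), _fake_segmentation(gt))

        shifted_img = np.roll(img.astype(float), (6, -9), axis=(0, 1))
        shifted_gt = phantom.GroundTruth(
            glottis_mask=np.roll(gt.glottis_mask, (6, -9), axis=(0, 1)),
            left_cord_mask=np.roll(gt.left_cord_mask, (6, -9), axis=(0, 1)),
            right_cord_mask=np.roll(gt.right_cord_mask, (6, -9), axis=(0, 1)),
            label=gt.label,
            lesion_side=gt.lesion_side,
        )
        fv_shift = features.extract_features(shifted_img, _fake_segmentation(shifted_gt))
        assert fv_shift == fv

        rot = lambda a: np.rot90(a, 2)
        rotated_gt = phantom.GroundTruth(
            glottis_mask=rot(gt.glottis_mask),
            left_cord_mask=rot(gt.right_cord_mask),  # 180 deg swaps the sides
            right_cord_mask=rot(gt.left_cord_mask),
            label=gt.label,
            lesion_side=gt.lesion_side,
        )
        fv_rot = features.extract_features(rot(img.astype(float)), _fake_segmentation(rotated_gt))
        assert fv_rot.left.gray_std == pytest.approx(fv.right.gray_std)
        assert fv_rot.left.max_deviation == pytest.approx(fv.right.max_deviation, abs=1.0)
        assert fv_rot.left.geometric_abnormal == fv.right.geometric_abnormal

    def test_feature_row_aggregates(self, analyzed_polyp):
        row = analyzed_polyp[2]["features"].to_row()
        assert set(features.FEATURE_COLUMNS) <= set(row)
        assert row["any_abnormal"] == 1.0
        assert row["max_deviation"] == max(row["left_max_deviation"], row["right_max_deviation"])
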