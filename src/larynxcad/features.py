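"""Geometric and hue features of the segmented vocal cords.

Three quantities discriminate the five conditions: (1) whether the cord's
medial (glottis-facing) edge protrudes beyond the straight line joining its
anterior- and posterior-most points — convex lesions (polyp, cyst) do;
(2) the length-to-width ratio of that protrusion — polyps are tall and
narrow, cysts broad and shallow; (3) the standard deviation of the gray
values inside the cord — white patches (leukoplakia) and heterogeneous
texture (tumor) both raise it.  Gray statistics are taken on the
brightness-compensated image so they are comparable across acquisitions;
being a pure shift, compensation leaves the standard deviation unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from larynxcad.config import FeatureConfig
from larynxcad.errors import DegenerateInputError
from larynxcad.segmentation import SegmentationResult


@dataclass
class CordFeatures:
    """Per-cord measurements."""

    geometric_abnormal: bool
    max_deviation: float  # px beyond the baseline, toward the glottis
    protrusion_length: float  # px (== max_deviation)
    protrusion_width: float  # px along the baseline
    lw_ratio: float  # protrusion length / width; 0 when not abnormal
    gray_std: float  # population std of gray values in the cord


@dataclass
class FeatureVector:
    """Both cords' features for one image."""

    left: CordFeatures
    right: CordFeatures

    def to_row(self) -> dict[str, float]:
        """Flat dict for feature tables, with per-image aggregates."""
        row: dict[str, float] = {}
        for side, cf in (("left", self.left), ("right", self.right)):
            for key, value in asdict(cf).items():
                row[f"{side}_{key}"] = float(value)
        dominant = self.left if self.left.max_deviation >= self.right.max_deviation else self.right
        row["any_abnormal"] = float(self.left.geometric_abnormal or self.right.geometric_abnormal)
        row["max_deviation"] = float(dominant.max_deviation)
        row["lw_ratio"] = float(dominant.lw_ratio)
        row["gray_std_max"] = float(max(self.left.gray_std, self.right.gray_std))
        return row


FEATURE_COLUMNS = [
    "left_geometric_abnormal",
    "left_max_deviation",
    "left_protrusion_length",
    "left_protrusion_width",
    "left_lw_ratio",
    "left_gray_std",
    "right_geometric_abnormal",
    "right_max_deviation",
    "right_protrusion_length",
    "right_protrusion_width",
    "right_lw_ratio",
    "right_gray_std",
    "any_abnormal",
    "max_deviation",
    "lw_ratio",
    "gray_std_max",
]


def medial_edge(
    cord_mask: np.ndarray,
    side: str,
    row_range: tuple[int, int] | None = None,
    trim: int = 0,
) -> np.ndarray:
    """(row, col) medial-edge points of a cord mask, one per occupied row.

    The medial edge faces the glottis: for the left cord it is the
    rightmost cord pixel of each row, for the right cord the leftmost.
    ``row_range`` restricts the measurement to the rows where the cord
    actually faces the glottis (the segmented contour has rounded caps
    beyond them), and ``trim`` drops that many additional rows at each end
    to avoid corner effects.
    """
    mask = np.asarray(cord_mask, dtype=bool)
    rows = np.nonzero(mask.any(axis=1))[0]
    if row_range is not None:
        lo, hi = row_range[0] + trim, row_range[1] - trim
        rows = rows[(rows >= lo) & (rows <= hi)]
    if rows.size < 2:
        raise DegenerateInputError("cord mask spans fewer than 2 rows")
    pts = np.empty((rows.size, 2))
    for i, r in enumerate(rows):
        cols = np.nonzero(mask[r])[0]
        pts[i] = (r, cols.max() if side == "left" else cols.min())
    return pts


def fit_cord_baseline(edge_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Straight line along the vocal fold.

    The line joins the anterior-most (first-row) and posterior-most
    (last-row) points of the medial edge; both endpoints lie on the edge.
    """
    pts = np.asarray(edge_points, dtype=float)
    if pts.shape[0] < 2:
        raise DegenerateInputError("need at least 2 edge points for a baseline")
    return pts[0].copy(), pts[-1].copy()


def protrusion_geometry(
    edge_points: np.ndarray,
    baseline: tuple[np.ndarray, np.ndarray],
    side: str,
    threshold: float = 0.0,
) -> tuple[float, float, float, float]:
    """(max_deviation, protrusion_length, protrusion_width, lw_ratio).

    Deviation is the signed distance of each medial-edge point beyond the
    baseline toward the glottis (positive = protruding medially).  The
    protrusion width is the extent, along the baseline, of the contiguous
    run of points whose deviation exceeds ``threshold`` and that contains
    the deviation maximum.  ``lw_ratio`` is 0 when nothing exceeds the
    threshold.
    """
    pts = np.asarray(edge_points, dtype=float)
    p0, p1 = baseline
    direction = p1 - p0
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise DegenerateInputError("degenerate baseline")
    direction = direction / norm
    # normal pointing toward the glottis: +col for the left cord, -col for the right
    normal = np.array([-direction[1], direction[0]])
    medial_sign = 1.0 if side == "left" else -1.0
    if np.sign(normal[1]) != medial_sign:
        normal = -normal
    dev = (pts - p0) @ normal
    max_dev = float(dev.max(initial=0.0))
    if max_dev <= 0:
        return 0.0, 0.0, 0.0, 0.0
    beyond = dev > threshold
    if not beyond.any():
        return max_dev, max_dev, 0.0, 0.0
    i_max = int(np.argmax(dev))
    lo = i_max
    while lo > 0 and beyond[lo - 1]:
        lo -= 1
    hi = i_max
    while hi < len(pts) - 1 and beyond[hi + 1]:
        hi += 1
    along = (pts - p0) @ direction
    width = float(abs(along[hi] - along[lo])) + 1.0
    lw_ratio = max_dev / width
    return max_dev, max_dev, width, lw_ratio


def cord_gray_std(image: np.ndarray, cord_mask: np.ndarray) -> float:
    """Population standard deviation of gray values under the cord mask."""
    mask = np.asarray(cord_mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty cord mask")
    return float(np.asarray(image, dtype=float)[mask].std())


def extract_cord(
    image: np.ndarray,
    cord_mask: np.ndarray,
    side: str,
    config: FeatureConfig | None = None,
    row_range: tuple[int, int] | None = None,
) -> CordFeatures:
    """All features of a single cord."""
    config = config or FeatureConfig()
    trim = 0
    if row_range is not None:
        trim = max(int(round((row_range[1] - row_range[0]) * 0.06)), 3)
    edge = medial_edge(cord_mask, side, row_range, trim)
    baseline = fit_cord_baseline(edge)
    cord_length = float(np.linalg.norm(baseline[1] - baseline[0]))
    threshold = config.deviation_threshold_px * cord_length / config.reference_cord_length
    max_dev, length, width, lw = protrusion_geometry(edge, baseline, side, threshold)
    abnormal = max_dev > threshold
    return CordFeatures(
        geometric_abnormal=bool(abnormal),
        max_deviation=max_dev,
        protrusion_length=length if abnormal else 0.0,
        protrusion_width=width if abnormal else 0.0,
        lw_ratio=lw if abnormal else 0.0,
        gray_std=cord_gray_std(image, cord_mask),
    )


def extract_features(
    image: np.ndarray,
    segmentation: SegmentationResult,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Features of both cords from a segmentation result.

    ``image`` should be the brightness-compensated (not CLAHE-enhanced)
    image so gray standard deviations are comparable across acquisitions.
    The medial edge is measured over the rows the glottis spans — only
    there does the cord have a glottis-facing edge.
    """
    rows = np.nonzero(np.asarray(segmentation.glottis_mask, dtype=bool).any(axis=1))[0]
    row_range = (int(rows[0]), int(rows[-1])) if rows.size else None
    return FeatureVector(
        left=extract_cord(image, segmentation.left_mask, "left", config, row_range),
        right=extract_cord(image, segmentation.right_mask, "right", config, row_range),
    )
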