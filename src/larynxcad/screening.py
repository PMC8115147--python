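"""Clearest-frame selection from a laryngoscopic sequence.

A frame is usable when it contains a well-formed glottal block: the glottic
space appears as a dark inverted triangle near the vertical centre of the
frame.  Candidate blocks come from thresholding with a fast Otsu search
(four sub-intervals delimited by the global mean and the two class means —
equivalent to the exhaustive search because the intervals cover the full
gray range) and are screened by three structural conditions: centroid row,
bounding-box aspect ratio, and minimum area.  Frames that differ too much
from their predecessor (low PSNR: motion or noise bursts) are discarded,
and among the survivors the frame with the largest screened glottal block
is selected as the clearest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from larynxcad.config import ScreeningThresholds
from larynxcad.errors import DegenerateInputError, NoCandidateError
from larynxcad.io import FrameSequence


@dataclass
class Region:
    """One 8-connected component of a binary mask."""

    label: int
    area: int
    centroid_x: float
    centroid_y: float
    bbox: tuple[int, int, int, int]  # (top, left, bottom, right), half-open
    aspect_ratio: float  # bbox width / bbox height


@dataclass
class FastOtsuState:
    """Intermediate quantities of the interval-restricted Otsu search."""

    icp_m: float  # global mean gray level
    icp_b: float  # mean of pixels below the global mean ("background")
    icp_f: float  # mean of pixels at/above the global mean ("foreground")
    intervals: tuple[tuple[int, int], ...]
    best_threshold: int
    best_variance: float


def psnr(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; identical frames return +inf."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = np.mean((a - b) ** 2)
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(255.0**2 / mse)


def _between_class_variance(hist: np.ndarray) -> np.ndarray:
    """sigma_b^2(t) for t = 0..254, class 0 being gray levels <= t."""
    levels = np.arange(256)
    total = hist.sum()
    p = hist / total
    omega0 = np.cumsum(p)[:-1]
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu[:-1] / omega0
        mu1 = (mu_total - mu[:-1]) / omega1
        var = omega0 * omega1 * (mu0 - mu1) ** 2
    return np.nan_to_num(var, nan=0.0)


def fast_otsu(image: np.ndarray, return_state: bool = False):
    """Otsu threshold via the four-interval restricted search.

    The search range [0, 255] is split at the background-class mean, the
    global mean and the foreground-class mean; the best between-class
    variance within each interval is computed and the global best of the
    four is returned.  Because the intervals tile the full range the result
    coincides with the exhaustive Otsu threshold (smallest maximiser on
    ties).  Pixels at gray levels <= threshold form the dark class.
    """
    img = np.asarray(image)
    img = np.clip(np.rint(img.astype(float)), 0, 255).astype(np.uint8)
    if img.min() == img.max():
        raise DegenerateInputError("constant image has no Otsu threshold")
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    icp_m = float(img.mean())
    below = img[img < icp_m]
    above = img[img >= icp_m]
    icp_b = float(below.mean()) if below.size else 0.0
    icp_f = float(above.mean()) if above.size else 255.0
    bounds = [0, int(np.floor(icp_b)), int(np.floor(icp_m)), int(np.floor(icp_f)), 254]
    intervals = tuple(
        (bounds[i], bounds[i + 1]) for i in range(4) if bounds[i] <= bounds[i + 1]
    )
    var = _between_class_variance(hist)
    best_t, best_v = 0, -1.0
    for lo, hi in intervals:
        seg = var[lo : hi + 1]
        t_local = lo + int(np.argmax(seg))
        v_local = float(seg.max())
        if v_local > best_v + 1e-12:
            best_t, best_v = t_local, v_local
        elif abs(v_local - best_v) <= 1e-12 and t_local < best_t:
            best_t = t_local
    if return_state:
        return best_t, FastOtsuState(icp_m, icp_b, icp_f, intervals, best_t, best_v)
    return best_t


def dark_mask(image: np.ndarray, threshold: int) -> np.ndarray:
    """Binary mask of the dark (sub-threshold) class — the glottal polarity."""
    img = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255)
    return img <= threshold


def label_regions(binary: np.ndarray) -> list[Region]:
    """8-connected components with area, centroid, bbox and aspect ratio."""
    mask = np.asarray(binary, dtype=bool)
    labeled = measure.label(mask, connectivity=2)
    regions = []
    for rp in measure.regionprops(labeled):
        top, left, bottom, right = rp.bbox
        height = bottom - top
        width = right - left
        cy, cx = rp.centroid
        regions.append(
            Region(
                label=int(rp.label),
                area=int(rp.area),
                centroid_x=float(cx),
                centroid_y=float(cy),
                bbox=(int(top), int(left), int(bottom), int(right)),
                aspect_ratio=float(width) / float(height),
            )
        )
    return regions


def screen_glottal_candidates(
    regions: list[Region],
    thresholds: ScreeningThresholds | None = None,
) -> list[Region]:
    """Keep regions satisfying the three glottal structure conditions.

    (1) centroid row within [centroid_y_min, centroid_y_max] — the glottis
    sits near the vertical centre; (2) bbox aspect ratio <= aspect_ratio_max
    — an inverted triangle is taller than wide, east-west elongated blocks
    are excluded; (3) area >= area_min pixels.  Order is preserved and the
    filter is idempotent.
    """
    thresholds = thresholds or ScreeningThresholds()
    return [
        r
        for r in regions
        if thresholds.centroid_y_min <= r.centroid_y <= thresholds.centroid_y_max
        and r.aspect_ratio <= thresholds.aspect_ratio_max
        and r.area >= thresholds.area_min
    ]


def largest_glottal_region(
    image: np.ndarray,
    thresholds: ScreeningThresholds | None = None,
) -> tuple[Region, np.ndarray]:
    """Largest screened dark region of one frame plus its pixel mask."""
    thresholds = (thresholds or ScreeningThresholds()).scaled(image.shape[0])
    t = fast_otsu(image)
    mask = dark_mask(image, t)
    labeled = measure.label(mask, connectivity=2)
    regions = screen_glottal_candidates(label_regions(mask), thresholds)
    if not regions:
        raise NoCandidateError("no region passed the glottal structure screening")
    best = max(regions, key=lambda r: r.area)
    return best, labeled == best.label


def select_clearest_frame(
    seq: FrameSequence,
    thresholds: ScreeningThresholds | None = None,
    psnr_min: float | None = None,
) -> tuple[int, Region]:
    """Index and glottal region of the clearest frame of a sequence.

    Frames whose PSNR to the preceding frame falls below ``psnr_min``
    (large inter-frame error: motion or noise) are discarded; the first
    frame has no predecessor and is always considered.  Each surviving
    frame contributes its largest screened glottal block, and the frame
    with the maximal block area wins (ties: earliest frame).
    """
    thresholds = thresholds or ScreeningThresholds()
    if psnr_min is None:
        psnr_min = thresholds.psnr_min
    if len(seq) == 0:
        raise NoCandidateError("empty frame sequence")
    best_idx, best_region = -1, None
    for k, frame in enumerate(seq.frames):
        if k > 0 and psnr(frame, seq.frames[k - 1]) < psnr_min:
            continue
        try:
            region, _ = largest_glottal_region(frame, thresholds)
        except (NoCandidateError, DegenerateInputError):
            continue
        if best_region is None or region.area > best_region.area:
            best_idx, best_region = k, region
    if best_region is None:
        raise NoCandidateError("no frame passed screening")
    return best_idx, best_region
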