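"""Glottis and vocal-cord segmentation with an adaptive active contour.

The glottis is segmented by thresholding (fast Otsu) plus the glottal
structure screening.  Each vocal cord is then segmented by a greedy snake
initialised from a seed band adjacent to the glottis boundary: a horizontal
transect through the glottic centroid and a vertical cut through the lowest
glottis point split the periglottic space into a left and a right seed.
The glottis pixels are removed from the image before cord evolution so the
contour cannot re-enter previously segmented territory.

Because lens distance changes the apparent cord size, the snake's iteration
count cannot be fixed.  Instead the contour is evolved to the upper bound
while recording the Shannon entropy of the enclosed ("growth") region; the
iteration at which the entropy difference between consecutive iterations is
minimal — the growth range has saturated — is selected, clamped to the
bounds [13, 41].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure

from larynxcad.config import ScreeningThresholds, SegmentationConfig, SnakeParams
from larynxcad.errors import DegenerateContourError, DegenerateInputError
from larynxcad.screening import largest_glottal_region

ITER_MIN_DEFAULT = 13
ITER_MAX_DEFAULT = 41


@dataclass
class EntropyTrace:
    """Entropy record driving the adaptive stopping rule.

    ``entropies[j]`` is the growth-range entropy after ``iter_min - 1 + j``
    snake sweeps (the first entry belongs to the iteration preceding
    ``iter_min``).  ``differences[k-1]`` compares candidate ``k``, i.e.
    iterations ``iter_min - 1 + k`` and ``iter_min - 2 + k``; the selected
    count is ``iter_min - 1 + k*`` with ``k*`` the 1-based argmin of the
    absolute differences (ties toward smaller ``k``).
    """

    iter_min: int = ITER_MIN_DEFAULT
    iter_max: int = ITER_MAX_DEFAULT
    entropies: np.ndarray = field(default_factory=lambda: np.array([]))
    differences: np.ndarray = field(default_factory=lambda: np.array([]))
    k_star: int = 0
    n_star: int = 0


@dataclass
class CordSeeds:
    """Left/right seed bands plus the glottis geometry they derive from."""

    left_mask: np.ndarray
    right_mask: np.ndarray
    glottis_mask: np.ndarray
    centroid_row: float
    lowest_point: tuple[int, float]  # (row, col) of the lowest glottis pixel


@dataclass
class SegmentationResult:
    """Masks, contours and per-cord adaptive iteration counts."""

    glottis_mask: np.ndarray
    left_contour: np.ndarray
    right_contour: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    left_iters: int
    right_iters: int
    left_trace: EntropyTrace
    right_trace: EntropyTrace
    provenance: dict = field(default_factory=dict)


def segment_glottis(
    image: np.ndarray,
    thresholds: ScreeningThresholds | None = None,
) -> np.ndarray:
    """Binary mask of the largest screened glottal block of one image."""
    _, mask = largest_glottal_region(image, thresholds)
    return mask


def extract_cord_seeds(
    glottis_mask: np.ndarray,
    config: SegmentationConfig | None = None,
) -> CordSeeds:
    """Seed bands for the left and right vocal cord.

    The band of pixels within ``seed_width`` of the glottis boundary
    (outside the glottis) is split by the vertical line through the lowest
    glottis point into the left and right seed; the horizontal transect
    through the glottic centroid optionally restricts the seeds to the rows
    below it (``seed_row_extent='below_centroid'``).  Seeds are disjoint,
    never overlap the glottis, and each touches the glottis boundary.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(glottis_mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty glottis mask")
    rows, cols = np.nonzero(mask)
    centroid_row = rows.mean()
    lowest_row = rows.max()
    lowest_col = cols[rows == lowest_row].mean()
    band = ndimage.binary_dilation(mask, iterations=config.seed_width) & ~mask
    rr = np.arange(mask.shape[0])[:, None]
    cc = np.arange(mask.shape[1])[None, :]
    row_lo = centroid_row if config.seed_row_extent == "below_centroid" else rows.min()
    in_rows = (rr >= row_lo) & (rr <= lowest_row)
    left = band & in_rows & (cc < lowest_col)
    right = band & in_rows & (cc > lowest_col)
    if not left.any() or not right.any():
        raise DegenerateInputError("seed construction produced an empty side")
    return CordSeeds(
        left_mask=left,
        right_mask=right,
        glottis_mask=mask,
        centroid_row=float(centroid_row),
        lowest_point=(int(lowest_row), float(lowest_col)),
    )


def _mask_to_contour(mask: np.ndarray, points: int) -> np.ndarray:
    """Closed (points, 2) float contour of the largest component of a mask."""
    labeled = measure.label(mask, connectivity=2)
    if labeled.max() > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        mask = labeled == (1 + int(np.argmax(sizes)))
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DegenerateContourError("mask has no traceable boundary")
    contour = max(contours, key=len)
    return resample_contour(contour, points)


def resample_contour(contour: np.ndarray, points: int) -> np.ndarray:
    """Resample a closed contour to ``points`` equally spaced vertices."""
    c = np.asarray(contour, dtype=float)
    if not np.allclose(c[0], c[-1]):
        c = np.vstack([c, c[:1]])
    seg = np.sqrt(((np.diff(c, axis=0)) ** 2).sum(axis=1))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise DegenerateContourError("zero-length contour")
    targets = np.linspace(0.0, total, points, endpoint=False)
    out = np.empty((points, 2))
    out[:, 0] = np.interp(targets, arclen, c[:, 0])
    out[:, 1] = np.interp(targets, arclen, c[:, 1])
    return out


def contour_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled-polygon mask of a closed contour."""
    rr, cc = draw.polygon(contour[:, 0], contour[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def gradient_energy(image: np.ndarray, sigma: float = 1.5, w_image: float = 1.0) -> np.ndarray:
    """External snake energy: negative normalised gradient magnitude."""
    img = np.asarray(image, dtype=float)
    grad = filters.sobel(ndimage.gaussian_filter(img, sigma))
    peak = grad.max()
    if peak > 0:
        grad = grad / peak
    return -w_image * grad


def _contour_energy(
    contour: np.ndarray,
    external: np.ndarray,
    params: SnakeParams,
    d_bar: float,
) -> float:
    prev_v = np.roll(contour, 1, axis=0)
    next_v = np.roll(contour, -1, axis=0)
    d = np.sqrt(((contour - prev_v) ** 2).sum(axis=1))
    cont = ((d - d_bar) / d_bar) ** 2
    curv = (((prev_v - 2 * contour + next_v) ** 2).sum(axis=1)) / d_bar**2
    r = np.clip(np.rint(contour[:, 0]).astype(int), 0, external.shape[0] - 1)
    c = np.clip(np.rint(contour[:, 1]).astype(int), 0, external.shape[1] - 1)
    ext = external[r, c]
    return float(np.sum(params.w_continuity * cont + params.w_curvature * curv + ext))


def acm_evolve(
    image: np.ndarray,
    init: np.ndarray,
    params: SnakeParams | None = None,
    n_iter: int = 1,
    external: np.ndarray | None = None,
    record_masks_from: int | None = None,
    record_contours: bool = False,
):
    """Greedy snake: per-vertex energy minimisation over a 3x3 neighbourhood.

    Each sweep visits every vertex once and moves it to the candidate
    position (offsets of ``params.step`` pixels) that lowers the total
    contour energy; moves that do not lower it are rejected, so the total
    energy is non-increasing within every sweep (the spacing normaliser
    ``d_bar`` is frozen at sweep start and the contour is resampled to
    uniform spacing between sweeps).  The energy is

        sum_i  w_continuity ((|v_i - v_{i-1}| - d_bar)/d_bar)^2
             + w_curvature |v_{i-1} - 2 v_i + v_{i+1}|^2 / d_bar^2
             + external(v_i)

    with ``external`` defaulting to the negative normalised gradient
    magnitude scaled by ``w_image``.  Returns the final contour and a list
    of per-sweep ``(start_energy, end_energy)`` pairs; optionally also the
    filled masks from sweep ``record_masks_from`` onward and the per-sweep
    contours.
    """
    params = params or SnakeParams()
    img = np.asarray(image, dtype=float)
    contour = np.asarray(init, dtype=float).copy()
    if np.allclose(contour[0], contour[-1]) and len(contour) > 1:
        contour = contour[:-1]
    if len(np.unique(np.rint(contour), axis=0)) < 3:
        raise DegenerateContourError("initial contour has fewer than 3 distinct vertices")
    if external is None:
        external = gradient_energy(img, w_image=params.w_image)
    h, w = external.shape
    offsets = np.array(
        [(dr, dc) for dr in (-params.step, 0.0, params.step) for dc in (-params.step, 0.0, params.step)]
    )
    energies: list[tuple[float, float]] = []
    masks: dict[int, np.ndarray] = {}
    contours: dict[int, np.ndarray] = {}
    n = len(contour)
    for sweep in range(1, n_iter + 1):
        d = np.sqrt(((contour - np.roll(contour, 1, axis=0)) ** 2).sum(axis=1))
        d_bar = max(float(d.mean()), 1e-6)
        e_start = _contour_energy(contour, external, params, d_bar)
        for i in range(n):
            prev_v = contour[(i - 1) % n]
            next_v = contour[(i + 1) % n]
            cand = contour[i] + offsets
            cand[:, 0] = np.clip(cand[:, 0], 1.0, h - 2.0)
            cand[:, 1] = np.clip(cand[:, 1], 1.0, w - 2.0)
            d_prev = np.sqrt(((cand - prev_v) ** 2).sum(axis=1))
            d_next = np.sqrt(((next_v - cand) ** 2).sum(axis=1))
            cont = ((d_prev - d_bar) / d_bar) ** 2 + ((d_next - d_bar) / d_bar) ** 2
            curv = ((prev_v - 2 * cand + next_v) ** 2).sum(axis=1) / d_bar**2
            # neighbouring curvature terms that involve v_i
            pp = contour[(i - 2) % n]
            nn = contour[(i + 2) % n]
            curv_prev = ((pp - 2 * prev_v + cand) ** 2).sum(axis=1) / d_bar**2
            curv_next = ((cand - 2 * next_v + nn) ** 2).sum(axis=1) / d_bar**2
            rr = np.clip(np.rint(cand[:, 0]).astype(int), 0, h - 1)
            cc = np.clip(np.rint(cand[:, 1]).astype(int), 0, w - 1)
            ext = external[rr, cc]
            local = (
                params.w_continuity * cont
                + params.w_curvature * (curv + curv_prev + curv_next)
                + ext
            )
            best = int(np.argmin(local))
            current = 4  # zero-offset candidate index
            if local[best] < local[current] - 1e-12:
                contour[i] = cand[best]
        e_end = _contour_energy(contour, external, params, d_bar)
        energies.append((e_start, e_end))
        if len(np.unique(np.rint(contour), axis=0)) < 3:
            raise DegenerateContourError(f"contour collapsed at sweep {sweep}")
        if record_masks_from is not None and sweep >= record_masks_from:
            masks[sweep] = contour_mask(contour, (h, w))
        if record_contours:
            contours[sweep] = contour.copy()
        # Re-distribute vertices only when spacing has drifted: a converged
        # contour must stay bit-identical between sweeps so the entropy
        # trace of a saturated growth range goes exactly flat.
        d_now = np.sqrt(((contour - np.roll(contour, 1, axis=0)) ** 2).sum(axis=1))
        if d_now.max() > 2.0 * d_now.mean() or d_now.min() < 0.25 * d_now.mean():
            contour = resample_contour(contour, n)
    out = [contour, energies]
    if record_masks_from is not None:
        out.append(masks)
    if record_contours:
        out.append(contours)
    return tuple(out)


def region_entropy(image: np.ndarray, mask: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin gray histogram under a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask has no entropy")
    values = np.clip(np.rint(np.asarray(image, dtype=float)[mask]), 0, 255).astype(int)
    counts = np.bincount(values, minlength=256)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def select_iteration(differences: np.ndarray, iter_min: int = ITER_MIN_DEFAULT) -> int:
    """Map the 1-based argmin of |entropy differences| to an iteration count.

    Candidate ``k`` corresponds to iteration ``iter_min - 1 + k``: with the
    lower bound 13, a minimal difference at the 23rd candidate selects
    iteration 35 (the growth range saturates between the 35th and 36th
    iteration).
    """
    diffs = np.abs(np.asarray(differences, dtype=float))
    if diffs.size == 0:
        raise ValueError("empty difference trace")
    k_star = int(np.argmin(diffs)) + 1
    return iter_min - 1 + k_star


def adaptive_iterations(
    image: np.ndarray,
    seed_contour: np.ndarray,
    params: SnakeParams | None = None,
    bounds: tuple[int, int] = (ITER_MIN_DEFAULT, ITER_MAX_DEFAULT),
    external: np.ndarray | None = None,
):
    """Adaptive iteration count via the minimum-entropy-difference rule.

    Evolves the contour to ``iter_max`` sweeps, computes the growth-range
    entropy from sweep ``iter_min - 1`` onward, and selects the iteration
    whose absolute entropy difference to the previous iteration is minimal
    (ties toward the smaller count).  Returns ``(n_star, trace, contour)``
    with the contour as it stood after ``n_star`` sweeps; ``n_star`` lies in
    ``[iter_min, iter_max]`` by construction.
    """
    params = params or SnakeParams()
    iter_min, iter_max = bounds
    _, energies, masks, contours = acm_evolve(
        image,
        seed_contour,
        params,
        n_iter=iter_max,
        external=external,
        record_masks_from=iter_min - 1,
        record_contours=True,
    )
    sweeps = list(range(iter_min - 1, iter_max + 1))
    entropies = np.array([region_entropy(image, masks[s]) for s in sweeps])
    differences = np.diff(entropies)
    n_star = select_iteration(differences, iter_min)
    trace = EntropyTrace(
        iter_min=iter_min,
        iter_max=iter_max,
        entropies=entropies,
        differences=differences,
        k_star=n_star - (iter_min - 1),
        n_star=n_star,
    )
    return n_star, trace, contours[n_star]


def segment_cords(
    image: np.ndarray,
    seeds: CordSeeds,
    params: SnakeParams | None = None,
    config: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Adaptive snake segmentation of both vocal cords.

    ``image`` should be the brightness-compensated image (CLAHE is not
    applied here: tile-wise equalisation exaggerates the cord/glottis edge
    relative to the cord/mucosa edge and destabilises the snake).  The
    already-segmented glottis is removed from further segmentation: its
    pixels are zeroed in the entropy image and carry a large positive
    energy barrier, so the contour cannot re-enter it.  Each cord evolves
    independently from its seed band with an outward balloon term (energy
    ``-w_balloon`` per pixel of distance from the seed), so the two
    adaptive iteration counts may differ.  Cord masks exclude the glottis
    by construction.
    """
    config = config or SegmentationConfig()
    params = params or config.snake
    smooth = ndimage.gaussian_filter(np.asarray(image, dtype=float), config.smooth_sigma)
    entropy_img = smooth.copy()
    entropy_img[seeds.glottis_mask] = 0.0
    # Normalise the edge map by the strongest gradients *away* from the
    # glottis rim: the cord/glottis edge is far stronger than the
    # cord/mucosa edge and would otherwise drown it out at low contrast.
    raw_grad = filters.sobel(ndimage.gaussian_filter(smooth, config.gradient_sigma))
    rim = ndimage.binary_dilation(seeds.glottis_mask, iterations=8)
    ref = np.quantile(raw_grad[~rim], 0.995)
    if ref <= 0:
        ref = max(raw_grad.max(), 1e-9)
    grad = -params.w_image * np.clip(raw_grad / ref, 0.0, 1.0)
    barrier = ndimage.binary_dilation(seeds.glottis_mask, iterations=1)
    sides = {}
    for name, seed_mask in (("left", seeds.left_mask), ("right", seeds.right_mask)):
        init = _mask_to_contour(seed_mask, params.points)
        balloon = ndimage.distance_transform_edt(~seed_mask)
        external = grad - config.w_balloon * balloon
        external[barrier] += config.barrier_energy
        n_star, trace, contour = adaptive_iterations(
            entropy_img,
            init,
            params,
            bounds=(config.iter_min, config.iter_max),
            external=external,
        )
        mask = contour_mask(contour, smooth.shape) & ~seeds.glottis_mask
        sides[name] = (contour, mask, n_star, trace)
    return SegmentationResult(
        glottis_mask=seeds.glottis_mask,
        left_contour=sides["left"][0],
        right_contour=sides["right"][0],
        left_mask=sides["left"][1],
        right_mask=sides["right"][1],
        left_iters=sides["left"][2],
        right_iters=sides["right"][2],
        left_trace=sides["left"][3],
        right_trace=sides["right"][3],
        provenance={
            "iter_bounds": [config.iter_min, config.iter_max],
            "w_balloon": config.w_balloon,
            "snake": {
                "w_continuity": params.w_continuity,
                "w_curvature": params.w_curvature,
                "w_image": params.w_image,
                "points": params.points,
            },
        },
    )


def relative_error(auto: float, reference: float) -> float:
    """Relative area error in percent: 100 |auto - reference| / reference."""
    if reference <= 0:
        raise ValueError("reference area must be positive")
    return 100.0 * abs(auto - reference) / reference
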