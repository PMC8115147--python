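"""Seeded synthetic laryngeal phantoms with ground truth.

The phantom emulates the geometry a laryngoscope sees: a dark inverted
triangle (the glottic space, apex pointing caudally/downward in the image),
flanked by two pale vocal-cord bands, on a mid-gray mucosal background with
a mild radial illumination falloff.  Lesions follow the phenomenology used
for classification: polyps and cysts are convex protrusions of the cord's
medial edge into the glottis (polyps narrow and tall, cysts broad and
shallow), leukoplakia is a bright patch on the cord, and tumors combine
intensity heterogeneity with a mildly irregular edge.

All randomness is drawn from a generator seeded by the spec, so identical
specs produce bit-identical images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from larynxcad.config import PhantomDefaults
from larynxcad.errors import InvalidSpecError

LABELS = ("healthy", "polyp", "cyst", "leukoplakia", "tumor")


@dataclass
class LesionSpec:
    """Parametric lesion model attached to one vocal cord."""

    label: str = "healthy"
    side: str = "left"
    protrusion_radius: float = 0.0  # medial protrusion depth, px (polyp/cyst)
    base_width: float = 0.0  # protrusion base along the cord, px
    patch_intensity: float = 0.0  # leukoplakia white-patch gray level
    texture_sigma: float = 0.0  # tumor intensity heterogeneity, gray levels
    edge_roughness: float = 0.0  # tumor medial-edge jitter amplitude, px

    def validate(self, cord_intensity: float) -> None:
        if self.label not in LABELS:
            raise InvalidSpecError(f"unknown lesion label: {self.label}")
        if self.side not in ("left", "right"):
            raise InvalidSpecError(f"lesion side must be left/right, got {self.side}")
        if self.label == "healthy":
            if self.protrusion_radius or self.base_width or self.patch_intensity or self.texture_sigma:
                raise InvalidSpecError("healthy lesion must have no geometry fields set")
        elif self.label in ("polyp", "cyst"):
            if self.protrusion_radius <= 0 or self.base_width <= 0:
                raise InvalidSpecError(f"{self.label} needs protrusion_radius > 0 and base_width > 0")
        elif self.label == "leukoplakia":
            if self.patch_intensity <= cord_intensity:
                raise InvalidSpecError("leukoplakia patch must be brighter than the cord")
        elif self.label == "tumor":
            if self.texture_sigma <= 0:
                raise InvalidSpecError("tumor needs texture_sigma > 0")


@dataclass
class PhantomSpec:
    """Full description of one synthetic laryngoscopic image."""

    image_height: int = 288
    image_width: int = 352
    glottis_apex: tuple[float, float] = (220.0, 176.0)  # (row, col), lowest point
    glottis_base: tuple[float, float, float] = (80.0, 138.0, 214.0)  # (row, col_left, col_right)
    glottis_intensity: float = 40.0
    cord_band_width: float = 26.0
    cord_intensity: float = 185.0
    background_intensity: float = 150.0
    lesion: LesionSpec | None = None
    illumination_offset: float = 0.0
    illumination_falloff: float = 20.0  # radial darkening at the frame corner
    noise_sigma: float = 4.0
    blur_sigma: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_height, self.image_width
        apex_r, apex_c = self.glottis_apex
        base_r, base_cl, base_cr = self.glottis_base
        if apex_r <= base_r:
            raise InvalidSpecError("glottis must be an inverted triangle: apex below base")
        if base_cl >= base_cr:
            raise InvalidSpecError("glottis base left column must be < right column")
        margin = self.cord_band_width + 2
        if not (0 <= base_r and apex_r < h and margin <= base_cl and base_cr < w - margin):
            raise InvalidSpecError("glottis triangle (plus cord bands) must lie inside the frame")
        for value in (
            self.glottis_intensity,
            self.cord_intensity,
            self.background_intensity,
        ):
            if not 0.0 <= value <= 255.0:
                raise InvalidSpecError("intensity means must be in [0, 255]")
        if self.lesion is not None:
            self.lesion.validate(self.cord_intensity)


@dataclass
class GroundTruth:
    """Pixel-exact reference produced alongside each phantom image."""

    glottis_mask: np.ndarray
    left_cord_mask: np.ndarray
    right_cord_mask: np.ndarray
    label: str
    lesion_side: str | None
    spec: PhantomSpec = field(repr=False, default=None)


def _edge_columns(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left/right glottis edge column (float) for each row the glottis spans."""
    apex_r, apex_c = spec.glottis_apex
    base_r, base_cl, base_cr = spec.glottis_base
    rows = np.arange(int(np.ceil(base_r)), int(np.floor(apex_r)) + 1)
    t = (rows - base_r) / (apex_r - base_r)
    left = base_cl + t * (apex_c - base_cl)
    right = base_cr + t * (apex_c - base_cr)
    return rows, left, right


def _half_ellipse(rows: np.ndarray, center: float, half_base: float, depth: float) -> np.ndarray:
    """Medial protrusion profile depth(row) for a half-elliptical bump."""
    u = (rows - center) / half_base
    prof = np.zeros_like(rows, dtype=float)
    inside = np.abs(u) < 1.0
    prof[inside] = depth * np.sqrt(1.0 - u[inside] ** 2)
    return prof


def generate_image(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom image and its ground truth.

    Returns an ``(image, ground_truth)`` pair where ``image`` is uint8 of
    shape (image_height, image_width).  Identical specs (including the seed)
    yield bit-identical pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    lesion = spec.lesion or LesionSpec()

    rows, left_edge, right_edge = _edge_columns(spec)
    n_rows = rows.size
    bump = np.zeros(n_rows)
    rough = np.zeros(n_rows)
    if lesion.label in ("polyp", "cyst"):
        center = rows[0] + 0.45 * (rows[-1] - rows[0])
        bump = _half_ellipse(rows, center, lesion.base_width / 2.0, lesion.protrusion_radius)
    if lesion.label == "tumor" and lesion.edge_roughness > 0:
        raw = rng.normal(0.0, 1.0, n_rows)
        smooth = ndimage.gaussian_filter1d(raw, 6.0)
        denom = np.max(np.abs(smooth))
        if denom > 0:
            rough = lesion.edge_roughness * smooth / denom
        rough = np.clip(rough, 0.0, None)  # protrude medially only

    # Medial (glottis-facing) cord edge per row, including lesion deformation.
    left_medial = left_edge.copy()
    right_medial = right_edge.copy()
    if lesion.side == "left":
        left_medial += bump + rough
    else:
        right_medial -= bump + rough

    cols = np.arange(w)[None, :]
    band = spec.cord_band_width
    lm = left_medial[:, None]
    rm = right_medial[:, None]
    le = left_edge[:, None]
    re_ = right_edge[:, None]

    # Glottis: between the (possibly deformed) medial edges.
    glottis_rows = (cols > lm) & (cols < rm)
    # Cords: lateral band of fixed width measured from the undeformed edge,
    # plus any medial protrusion carved out of the glottis.
    left_rows = (cols > le - band) & (cols <= lm)
    # near the apex the medial edges meet; the shared column goes left
    right_rows = (cols >= rm) & (cols < re_ + band) & ~left_rows

    glottis_mask = np.zeros((h, w), dtype=bool)
    left_mask = np.zeros((h, w), dtype=bool)
    right_mask = np.zeros((h, w), dtype=bool)
    glottis_mask[rows] = glottis_rows
    left_mask[rows] = left_rows
    right_mask[rows] = right_rows

    img = np.full((h, w), spec.background_intensity, dtype=float)
    img[left_mask | right_mask] = spec.cord_intensity
    img[glottis_mask] = spec.glottis_intensity

    if lesion.label == "leukoplakia":
        target = left_mask if lesion.side == "left" else right_mask
        rr, cc = np.nonzero(target)
        r0 = 0.45 * rr.min() + 0.55 * rr.max()
        c0 = cc.mean()
        patch = ((np.arange(h)[:, None] - r0) / 24.0) ** 2 + ((cols - c0) / (0.9 * band)) ** 2 <= 1.0
        img[patch & target] = lesion.patch_intensity
    if lesion.label == "tumor":
        target = left_mask if lesion.side == "left" else right_mask
        texture = rng.normal(0.0, lesion.texture_sigma, size=(h, w))
        texture = ndimage.gaussian_filter(texture, 1.2)
        # renormalise so the smoothed field keeps the requested sigma
        s = texture[target].std()
        if s > 0:
            texture *= lesion.texture_sigma / s
        img[target] += texture[target]

    if spec.illumination_falloff:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - h / 2.0) / (h / 2.0)) ** 2 + ((xx - w / 2.0) / (w / 2.0)) ** 2
        img -= spec.illumination_falloff * r2 / 2.0
    img += spec.illumination_offset

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        glottis_mask=glottis_mask,
        left_cord_mask=left_mask,
        right_cord_mask=right_mask,
        label=lesion.label,
        lesion_side=None if lesion.label == "healthy" else lesion.side,
        spec=spec,
    )
    return img, gt


def generate_sequence(
    spec: PhantomSpec,
    n_frames: int,
    blur_schedule: Sequence[float],
    jitter: float = 0.0,
) -> list[np.ndarray]:
    """Render a frame sequence with per-frame blur and integer-pixel jitter.

    Frame ``k`` is the base phantom blurred with ``blur_schedule[k]`` and
    translated by a seeded integer offset of magnitude up to ``jitter``
    (edge-padded).  The sharpest frame therefore shows the largest dark
    glottal block after thresholding, which is what frame screening relies on.
    """
    if n_frames != len(blur_schedule):
        raise InvalidSpecError(
            f"n_frames ({n_frames}) must equal len(blur_schedule) ({len(blur_schedule)})"
        )
    if n_frames == 0:
        raise InvalidSpecError("empty blur schedule")
    base_spec = dataclasses.replace(spec, blur_sigma=0.0, noise_sigma=0.0)
    base, _ = generate_image(base_spec)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for blur in blur_schedule:
        frame = base.astype(float)
        if blur > 0:
            frame = ndimage.gaussian_filter(frame, blur)
        if jitter > 0:
            dy, dx = rng.integers(-int(jitter), int(jitter) + 1, size=2)
            frame = ndimage.shift(frame, (dy, dx), order=0, mode="nearest")
        else:
            rng.integers(0, 1, size=2)  # keep the stream position schedule-independent
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames.append(np.clip(np.rint(frame), 0, 255).astype(np.uint8))
    return frames


def _sample_spec(rng: np.random.Generator, label: str, ranges: PhantomDefaults) -> PhantomSpec:
    u = rng.uniform
    half_base = u(*ranges.half_base)
    height = u(*ranges.glottis_height)
    cx = 176.0 + u(-ranges.center_jitter, ranges.center_jitter)
    base_r = u(70.0, 90.0)
    cord_int = u(*ranges.cord_intensity)
    side = "left" if rng.random() < 0.5 else "right"
    lesion: LesionSpec | None = None
    if label == "polyp":
        lesion = LesionSpec(
            label="polyp",
            side=side,
            protrusion_radius=u(*ranges.polyp_radius),
            base_width=u(*ranges.polyp_base),
        )
    elif label == "cyst":
        lesion = LesionSpec(
            label="cyst",
            side=side,
            protrusion_radius=u(*ranges.cyst_radius),
            base_width=u(*ranges.cyst_base),
        )
    elif label == "leukoplakia":
        lesion = LesionSpec(
            label="leukoplakia",
            side=side,
            patch_intensity=max(u(*ranges.leukoplakia_intensity), cord_int + 40.0),
        )
    elif label == "tumor":
        lesion = LesionSpec(
            label="tumor",
            side=side,
            texture_sigma=u(*ranges.tumor_texture_sigma),
            edge_roughness=u(1.0, 2.5),
        )
    return PhantomSpec(
        glottis_apex=(base_r + height, cx),
        glottis_base=(base_r, cx - half_base, cx + half_base),
        glottis_intensity=u(*ranges.glottis_intensity),
        cord_band_width=u(*ranges.cord_band_width),
        cord_intensity=cord_int,
        background_intensity=u(*ranges.background_intensity),
        lesion=lesion,
        illumination_offset=u(*ranges.illumination_offset),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_benchmark(
    n_per_class: int,
    seed: int,
    ranges: PhantomDefaults | None = None,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Balanced five-class dataset of (image, ground truth) pairs.

    Class-conditional parameter ranges live in :class:`PhantomDefaults` and
    are sampled from a generator seeded by ``seed``; re-running with the
    same arguments reproduces the dataset exactly.
    """
    if n_per_class < 1:
        raise InvalidSpecError("n_per_class must be >= 1")
    ranges = ranges or PhantomDefaults()
    rng = np.random.default_rng(seed)
    dataset = []
    for label in LABELS:
        for _ in range(n_per_class):
            spec = _sample_spec(rng, label, ranges)
            dataset.append(generate_image(spec))
    return dataset


def save_benchmark(dataset: list[tuple[np.ndarray, GroundTruth]], out_dir: str | Path) -> Path:
    """Write benchmark images as PNG + JSON ground-truth sidecars + CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["filename,label,seed"]
    for i, (img, gt) in enumerate(dataset):
        name = f"phantom_{i:04d}.png"
        iio.imwrite(out / name, img)
        sidecar = {
            "label": gt.label,
            "lesion_side": gt.lesion_side,
            "glottis_area": int(gt.glottis_mask.sum()),
            "left_cord_area": int(gt.left_cord_mask.sum()),
            "right_cord_area": int(gt.right_cord_mask.sum()),
            "seed": gt.spec.seed,
        }
        (out / f"phantom_{i:04d}.json").write_text(json.dumps(sidecar, indent=1))
        lines.append(f"{name},{gt.label},{gt.spec.seed}")
    manifest = out / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
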