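"""Configuration objects for every pipeline stage.

Every parameter has a default, so ``RunConfig()`` is a complete, valid
configuration.  YAML files override defaults block-wise; CLI flags override
the file (precedence: flags > file > defaults).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class CompensationParams:
    """Histogram-translation brightness compensation.

    ``set_value`` is the target mean grayscale; 125 avoids over-compensation
    of typical laryngoscopic exposures.  When ``clip`` is true the shifted
    values are bounded to [0, 255].
    """

    set_value: float = 125.0
    clip: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.set_value <= 255.0:
            raise ValueError(f"set_value must be in [0, 255], got {self.set_value}")


@dataclass
class EnhanceParams:
    """CLAHE followed by Gaussian smoothing.

    ``clahe_clip_limit`` uses the conventional histogram-multiple scale
    (2.0 means each tile histogram bin is clipped at twice the uniform
    level); internally it is mapped to scikit-image's normalised clip limit.
    ``gaussian_kernel`` is the odd side length of the smoothing template and
    bounds the Gaussian support; ``gaussian_sigma`` is its standard
    deviation in pixels.
    """

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gaussian_sigma: float = 1.0
    gaussian_kernel: int = 5

    def __post_init__(self) -> None:
        if self.clahe_tile_grid[0] < 1 or self.clahe_tile_grid[1] < 1:
            raise ValueError("clahe_tile_grid must be at least (1, 1)")
        if self.gaussian_kernel < 3 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd and >= 3")


@dataclass
class ScreeningThresholds:
    """Glottal structure conditions used to screen candidate regions.

    The centroid-row bounds are calibrated for ``reference_height``-row
    frames and are rescaled proportionally for other frame heights; aspect
    ratio (bbox width / height) and minimum area are resolution-relative
    quantities kept fixed.
    """

    centroid_y_min: float = 50.0
    centroid_y_max: float = 240.0
    aspect_ratio_max: float = 0.85
    area_min: float = 900.0
    reference_height: int = 288
    psnr_min: float = 20.0

    def __post_init__(self) -> None:
        if self.centroid_y_min >= self.centroid_y_max:
            raise ValueError("centroid_y_min must be < centroid_y_max")
        if min(self.centroid_y_min, self.aspect_ratio_max, self.area_min) <= 0:
            raise ValueError("screening thresholds must be positive")

    def scaled(self, image_height: int) -> "ScreeningThresholds":
        """Return thresholds with centroid bounds rescaled to ``image_height``."""
        f = image_height / self.reference_height
        return dataclasses.replace(
            self,
            centroid_y_min=self.centroid_y_min * f,
            centroid_y_max=self.centroid_y_max * f,
            reference_height=image_height,
        )


@dataclass
class SnakeParams:
    """Greedy active-contour weights.

    The internal terms (continuity, curvature) are normalised by the mean
    vertex spacing so the weights are scale-free; ``w_image`` multiplies the
    negative normalised gradient magnitude.  ``step`` is the per-sweep vertex
    search radius in pixels and ``points`` the number of contour vertices.
    """

    w_continuity: float = 0.5
    w_curvature: float = 0.1
    w_image: float = 3.0
    step: float = 1.0
    points: int = 80

    def __post_init__(self) -> None:
        if min(self.w_continuity, self.w_curvature, self.w_image) < 0:
            raise ValueError("snake weights must be >= 0")
        if self.points < 8:
            raise ValueError("a snake needs at least 8 vertices")


@dataclass
class SegmentationConfig:
    """Adaptive vocal-cord segmentation settings.

    ``iter_min``/``iter_max`` bound the adaptive iteration count selected by
    the entropy-difference rule.  ``w_balloon`` is the outward inflation
    energy gained per pixel of distance from the seed region; it must stay
    below the image-energy drop at a true boundary or the contour leaks.
    """

    snake: SnakeParams = field(default_factory=SnakeParams)
    iter_min: int = 13
    iter_max: int = 41
    seed_width: int = 9
    seed_row_extent: str = "full"  # or "below_centroid"
    w_balloon: float = 0.18
    gradient_sigma: float = 1.2
    smooth_sigma: float = 1.0
    barrier_energy: float = 6.0

    def __post_init__(self) -> None:
        if not 1 <= self.iter_min <= self.iter_max:
            raise ValueError("need 1 <= iter_min <= iter_max")
        if self.seed_row_extent not in ("full", "below_centroid"):
            raise ValueError("seed_row_extent must be 'full' or 'below_centroid'")


@dataclass
class FeatureConfig:
    """Geometric-abnormality thresholding.

    A cord is geometrically abnormal when its medial edge protrudes beyond
    the anterior-posterior baseline by more than ``deviation_threshold_px``
    (quoted at ``reference_cord_length`` and scaled linearly with the
    measured cord length, so lens distance does not change the verdict).
    """

    deviation_threshold_px: float = 3.0
    reference_cord_length: float = 100.0


@dataclass
class ClassifyConfig:
    """Decision-tree SVM settings (RBF kernel at every node)."""

    kernel: str = "rbf"
    C: float = 10.0
    gamma: str = "scale"
    cv_folds: int = 10


@dataclass
class PhantomDefaults:
    """Benchmark parameter ranges per lesion class.

    These ranges define the synthetic study conditions: geometry jitter is
    shared by all classes, lesion-specific ranges keep noiseless classes
    separable by the three features (protrusion geometry, length-to-width
    ratio, grayscale standard deviation).
    """

    half_base: tuple[float, float] = (32.0, 44.0)
    glottis_height: tuple[float, float] = (125.0, 155.0)
    cord_band_width: tuple[float, float] = (22.0, 30.0)
    center_jitter: float = 10.0
    glottis_intensity: tuple[float, float] = (35.0, 50.0)
    cord_intensity: tuple[float, float] = (178.0, 192.0)
    background_intensity: tuple[float, float] = (143.0, 158.0)
    illumination_offset: tuple[float, float] = (-20.0, 20.0)
    polyp_radius: tuple[float, float] = (10.0, 14.0)
    polyp_base: tuple[float, float] = (14.0, 20.0)
    cyst_radius: tuple[float, float] = (6.0, 9.0)
    cyst_base: tuple[float, float] = (26.0, 36.0)
    leukoplakia_intensity: tuple[float, float] = (228.0, 245.0)
    tumor_texture_sigma: tuple[float, float] = (15.0, 22.0)


@dataclass
class RunConfig:
    """Aggregate configuration for a pipeline run."""

    compensation: CompensationParams = field(default_factory=CompensationParams)
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    screening: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    phantom: PhantomDefaults = field(default_factory=PhantomDefaults)
    seed: int = 0
    version: str = "1"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        cfg = cls()
        for block_name, block_value in data.items():
            if not hasattr(cfg, block_name):
                raise ValueError(f"unknown config block: {block_name}")
            current = getattr(cfg, block_name)
            if dataclasses.is_dataclass(current) and isinstance(block_value, dict):
                merged = _merge_dataclass(current, block_value)
                setattr(cfg, block_name, merged)
            else:
                setattr(cfg, block_name, block_value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _merge_dataclass(obj: Any, overrides: dict[str, Any]) -> Any:
    kwargs = {}
    for f in dataclasses.fields(obj):
        if f.name in overrides:
            value = overrides[f.name]
            current = getattr(obj, f.name)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                value = _merge_dataclass(current, value)
            elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
                value = tuple(value)
            kwargs[f.name] = value
        else:
            kwargs[f.name] = getattr(obj, f.name)
    unknown = set(overrides) - {f.name for f in dataclasses.fields(obj)}
    if unknown:
        raise ValueError(f"unknown config keys for {type(obj).__name__}: {sorted(unknown)}")
    return type(obj)(**kwargs)
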