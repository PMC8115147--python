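"""Brightness compensation and contrast enhancement.

Laryngoscope lens distance varies during acquisition, so exposure differs
between images.  Histogram translation shifts every pixel by the same
offset ``S - O_m`` (target mean minus current mean), giving all images a
comparable brightness range before segmentation and hue analysis.  CLAHE
plus Gaussian smoothing then raise local contrast and suppress noise.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure

from larynxcad.config import CompensationParams, EnhanceParams
from larynxcad.errors import DegenerateInputError


def compensate_brightness(
    image: np.ndarray,
    params: CompensationParams | None = None,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Shift every pixel by ``S - O_m`` so the image mean becomes ``S``.

    ``O_m`` is the mean of the input image; when ``valid_mask`` is given
    (e.g. to exclude the endoscope's black circular border, which is set to
    gray level 0), only pixels under the mask contribute to ``O_m``.  The
    result is returned as float64 so that, absent clipping, its mean equals
    ``S`` exactly; quantise with :func:`to_uint8` when an 8-bit raster is
    needed.
    """
    params = params or CompensationParams()
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise DegenerateInputError("empty image")
    if valid_mask is not None:
        mask = np.asarray(valid_mask, dtype=bool)
        if not mask.any():
            raise DegenerateInputError("validity mask excludes every pixel")
        o_m = img[mask].mean()
    else:
        o_m = img.mean()
    out = img + (params.set_value - o_m)
    if params.clip:
        out = np.clip(out, 0.0, 255.0)
    return out


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Round and clip a float image to an 8-bit raster."""
    return np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.uint8)


def enhance(image: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """CLAHE (tile-wise, clip-limited) followed by Gaussian smoothing.

    The clip limit is quoted on the histogram-multiple scale and divided by
    256 to obtain scikit-image's normalised clip limit.  Returns uint8.
    """
    params = params or EnhanceParams()
    img = to_uint8(image)
    if img.ndim != 2:
        raise DegenerateInputError("enhance expects a 2-D grayscale image")
    if img.max() != img.min():
        rows = max(img.shape[0] // params.clahe_tile_grid[0], 1)
        cols = max(img.shape[1] // params.clahe_tile_grid[1], 1)
        eq = exposure.equalize_adapthist(
            img,
            kernel_size=(rows, cols),
            clip_limit=params.clahe_clip_limit / 256.0,
        )
        img = np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    smoothed = gaussian_smooth(img, params)
    return to_uint8(smoothed)


def gaussian_smooth(image: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Gaussian smoothing with an odd ``gaussian_kernel`` bounding the support.

    ``sigma <= 0`` degenerates to the identity (impulse template).
    """
    params = params or EnhanceParams()
    if params.gaussian_kernel % 2 == 0 or params.gaussian_kernel < 3:
        raise ValueError("gaussian_kernel must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    if params.gaussian_sigma <= 0:
        return img.copy()
    radius = (params.gaussian_kernel - 1) // 2
    return ndimage.gaussian_filter(img, params.gaussian_sigma, radius=radius, mode="nearest")
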