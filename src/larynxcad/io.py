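"""Readers and writers for images, frame sequences, masks and run reports.

Coordinate convention used throughout the package: row-major arrays, origin
at the top-left, 0-based indices, y (row) increasing downward.  The "lowest
point" of a structure is therefore the pixel with the maximal row index.
RGB inputs are converted to grayscale with the Rec. 601 luma weighting.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

from larynxcad.errors import FormatError

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered frames from a video or a directory of numbered images."""

    frames: list[np.ndarray]
    source: str = ""
    fps: float | None = None
    rgb_frames: list[np.ndarray] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, idx: int) -> np.ndarray:
        return self.frames[idx]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """8-bit grayscale view of an image, luma-converting RGB(A) input."""
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        gray = image[..., :3].astype(float) @ _LUMA
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise FormatError(f"unsupported image shape {image.shape}")


def natural_key(name: str) -> list[object]:
    """Sort key splitting digit runs so f2 < f10."""
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single image file as 8-bit grayscale."""
    try:
        raw = iio.imread(Path(path))
    except (OSError, ValueError, RuntimeError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    return to_grayscale(np.asarray(raw))


def read_frames(path: str | Path) -> FrameSequence:
    """Read a video file, an image file, or a directory of numbered frames.

    Directory entries are ordered by natural numeric order of their file
    names.  All frames must share a single height and width.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES),
            key=lambda p: natural_key(p.name),
        )
        if not files:
            raise FormatError(f"no image files found in directory {path}")
        frames = [read_image(p) for p in files]
    elif path.suffix.lower() in IMAGE_SUFFIXES:
        frames = [read_image(path)]
    else:
        try:
            raw = iio.imread(path, plugin="pyav")
        except Exception as exc:  # codec availability varies
            raise FormatError(f"cannot decode video {path}: {exc}") from exc
        frames = [to_grayscale(np.asarray(f)) for f in np.atleast_3d(raw)]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"mixed frame sizes in {path}: {sorted(shapes)}")
    return FrameSequence(frames=frames, source=str(path))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as single-channel 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask back to boolean."""
    return to_grayscale(iio.imread(Path(path))) > 127


def write_feature_table(rows: list[dict[str, Any]], path: str | Path) -> None:
    """Write a feature table as CSV (one row per image)."""
    import pandas as pd

    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_feature_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(Path(path))


def write_report(result: dict[str, Any], path: str | Path) -> None:
    """Write a JSON run report; numpy scalars/arrays are converted to lists."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True, default=_jsonify)


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
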