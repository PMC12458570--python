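"""Frame decoding and basic image plumbing.

A *video* here is either a multi-page TIFF stack (lossless, the container the
synthetic generator writes) or a directory of still images sorted
lexicographically; single PNG/JPEG stills are also accepted.  Frames are
converted to float RGB in [0, 1] at decode time so every downstream stage
shares one numeric contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["Frame", "read_frames", "to_grayscale", "write_frame_png"]

_STILL_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

# BT.601 luma weights, the common video-decoding convention
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Frame:
    """One RGB frame with its position in the source video."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    frame_index: int
    timestamp: float | None = None


def _to_unit_rgb(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
    return np.clip(arr, 0.0, 1.0)


def read_frames(path: str | Path, stride: int = 1) -> Iterator[Frame]:
    """Yield frames in temporal order, keeping indices ``i % stride == 0``.

    The original frame index is preserved in ``Frame.frame_index`` so scores
    computed on a strided subset still refer to source positions.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _STILL_SUFFIXES
        )
        if not files:
            raise ValueError(f"no image files found in directory {path}")
        import imageio.v3 as iio

        for i, f in enumerate(files):
            if i % stride == 0:
                yield Frame(_to_unit_rgb(iio.imread(f)), i)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 3 and stack.shape[-1] in (3, 4):
            stack = stack[None]  # single frame
        for i, frame in enumerate(stack):
            if i % stride == 0:
                yield Frame(_to_unit_rgb(frame), i)
    elif path.suffix.lower() in _STILL_SUFFIXES:
        import imageio.v3 as iio

        yield Frame(_to_unit_rgb(iio.imread(path)), 0)
    else:
        raise ValueError(
            f"cannot decode {path}: supported inputs are TIFF stacks, "
            "image directories and PNG/JPEG stills"
        )


def to_grayscale(frame: Frame | np.ndarray) -> np.ndarray:
    """BT.601 luminance in [0, 1], same height/width as the input."""
    image = frame.image if isinstance(frame, Frame) else np.asarray(frame)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    return np.clip(image @ _LUMA, 0.0, 1.0)


def write_frame_png(frame: Frame | np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    image = frame.image if isinstance(frame, Frame) else np.asarray(frame)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.clip(image, 0, 1) * 255).round().astype(np.uint8))
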