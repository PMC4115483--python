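"""Grayscale midsagittal frame container and image I/O.

Coordinates are 0-based ``(row, col)`` with the row index increasing
downward and the anterior direction toward smaller column indices.
All geometry is kept in pixels; conversion to millimetres happens only
at measurement time via the frame's ``resolution`` (pixels per mm).
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

#: Spatial resolution of the acquisition protocol this package targets,
#: in pixels per millimetre (256x256 matrix over a 36 cm field of view).
DEFAULT_RESOLUTION = 1.057


@dataclass
class Frame:
    """A single grayscale midsagittal image frame.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Non-negative, finite intensities (any numeric dtype; stored as float).
    resolution : float
        Pixels per millimetre. Must be positive.
    frame_index : int
        Position of the frame within its acquisition sequence.
    """

    pixels: np.ndarray
    resolution: float = DEFAULT_RESOLUTION
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("frame pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame intensities must be finite")
        if np.any(px < 0):
            raise ValueError("frame intensities must be non-negative")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive (pixels per mm)")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def px_to_mm(self, distance_px: float) -> float:
        """Convert a pixel distance to millimetres."""
        return float(distance_px) / self.resolution


def load_frame(path: str, resolution: float = DEFAULT_RESOLUTION,
               frame_index: int = 0) -> Frame:
    """Read a PNG/TIFF grayscale image as a :class:`Frame`.

    RGB(A) inputs are collapsed to luminance by channel averaging.
    """
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return Frame(arr, resolution=resolution, frame_index=frame_index)


def load_frame_sequence(paths_or_glob, resolution: float = DEFAULT_RESOLUTION):
    """Read an ordered frame sequence from a file list or a glob pattern."""
    if isinstance(paths_or_glob, (str, os.PathLike)):
        paths = sorted(glob.glob(str(paths_or_glob)))
    else:
        paths = [str(p) for p in paths_or_glob]
    if not paths:
        raise FileNotFoundError("no frames matched the given paths")
    return [load_frame(p, resolution=resolution, frame_index=i)
            for i, p in enumerate(paths)]


def save_mask_png(mask: np.ndarray, path: str) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255)."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
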