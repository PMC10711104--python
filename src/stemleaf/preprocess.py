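"""Image cleanup before training/inference: cropping and median filtering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FilterWindow", "crop", "median_filter"]

_SHAPES = ("square", "cross", "line")


@dataclass(frozen=True)
class FilterWindow:
    """Median-filter window: shape and odd side length p (m = (p-1)/2)."""

    size: int = 3
    shape: str = "square"

    def __post_init__(self):
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"window size must be odd and >= 3, got {self.size}")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")

    @property
    def half(self) -> int:
        return (self.size - 1) // 2

    def footprint(self) -> np.ndarray:
        p = self.size
        if self.shape == "square":
            return np.ones((p, p), dtype=bool)
        fp = np.zeros((p, p), dtype=bool)
        m = self.half
        fp[m, :] = True  # 1-D horizontal window (the "line" shape)
        if self.shape == "cross":
            fp[:, m] = True
        return fp


def crop(image: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Sub-raster at (left, top, width, height); 0-based, half-open."""
    image = np.asarray(image)
    left, top, width, height = (int(v) for v in box)
    if width <= 0 or height <= 0:
        raise ValueError("crop width/height must be positive")
    h, w = image.shape[:2]
    if left < 0 or top < 0 or left + width > w or top + height > h:
        raise ValueError(f"crop box {box} exceeds image bounds {(w, h)}")
    return image[top : top + height, left : left + width].copy()


def median_filter(image: np.ndarray, window: FilterWindow | int = 3) -> np.ndarray:
    """Replace each pixel by the median of its window (reflect padding).

    Multi-channel images are filtered per channel.
    """
    if isinstance(window, int):
        window = FilterWindow(size=window)
    image = np.asarray(image)
    fp = window.footprint()
    if image.ndim == 2:
        return ndimage.median_filter(image, footprint=fp, mode="reflect")
    if image.ndim == 3:
        out = np.empty_like(image)
        for c in range(image.shape[2]):
            out[..., c] = ndimage.median_filter(image[..., c], footprint=fp, mode="reflect")
        return out
    raise ValueError("expected a 2-D or 3-D raster")
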