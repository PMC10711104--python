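"""Post-segmentation trait extraction.

HSV colour-range region selection, Otsu binarization, crown-area
estimation (half of height x crown width), stem/leaf pixel proportions,
and predicted-vs-actual least-squares regression.

HSV follows the OpenCV scale: H in [0, 180], S and V in [0, 255], with
values quantized to integers before interval tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from skimage import color as skcolor

__all__ = [
    "HsvRange",
    "PhenotypeRecord",
    "class_proportions",
    "crown_area",
    "default_hsv_table",
    "fit_predicted_vs_actual",
    "hsv_mask",
    "load_hsv_table",
    "otsu_threshold",
    "rgb_to_hsv180",
]

STEM, LEAF = 1, 2


@dataclass(frozen=True)
class HsvRange:
    """Named colour range: hue intervals on 0-180, S/V intervals on 0-255."""

    name: str
    hue: tuple[tuple[int, int], ...]
    sat: tuple[int, int]
    val: tuple[int, int]

    def __post_init__(self):
        for lo, hi in self.hue:
            if not (0 <= lo <= hi <= 180):
                raise ValueError(f"{self.name}: hue interval {(lo, hi)} out of [0, 180]")
        for lo, hi in (self.sat, self.val):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{self.name}: S/V interval {(lo, hi)} out of [0, 255]")


def load_hsv_table(source) -> dict[str, HsvRange]:
    """Parse a colour-table mapping (YAML path or pre-parsed dict)."""
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    table = {}
    for name, spec in source.items():
        table[name] = HsvRange(
            name=name,
            hue=tuple((int(lo), int(hi)) for lo, hi in spec["hue"]),
            sat=tuple(int(v) for v in spec["sat"]),
            val=tuple(int(v) for v in spec["val"]),
        )
    return table


def default_hsv_table() -> dict[str, HsvRange]:
    ref = importlib.resources.files("stemleaf") / "data" / "hsv_ranges.yaml"
    return load_hsv_table(yaml.safe_load(ref.read_text()))


def rgb_to_hsv180(image: np.ndarray) -> np.ndarray:
    """uint8/float RGB -> integer HSV with H in 0..180, S/V in 0..255."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB raster (H, W, 3)")
    rgb = image.astype(np.float64) / (255.0 if image.dtype.kind in "iu" else 1.0)
    hsv = skcolor.rgb2hsv(rgb)
    out = np.empty(hsv.shape, dtype=np.int64)
    out[..., 0] = np.round(hsv[..., 0] * 180.0)
    out[..., 1] = np.round(hsv[..., 1] * 255.0)
    out[..., 2] = np.round(hsv[..., 2] * 255.0)
    return out


def hsv_mask(image: np.ndarray, rng: HsvRange) -> np.ndarray:
    """Boolean mask of pixels inside the colour range."""
    hsv = rgb_to_hsv180(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    in_hue = np.zeros(h.shape, dtype=bool)
    for lo, hi in rng.hue:
        in_hue |= (h >= lo) & (h <= hi)
    return (
        in_hue
        & (s >= rng.sat[0])
        & (s <= rng.sat[1])
        & (v >= rng.val[0])
        & (v <= rng.val[1])
    )


def otsu_threshold(gray: np.ndarray) -> int:
    """Exhaustive between-class-variance sweep over T in 0..255.

    Classes are {g <= T} and {g > T}; ties resolved to the smallest T.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    if gray.min() < 0 or gray.max() > 255:
        raise ValueError("expected 8-bit gray levels in 0..255")
    hist = np.bincount(gray.astype(np.int64).ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 gray levels")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w1 = np.cumsum(hist)  # mass of class {g <= T}
    m1 = np.cumsum(hist * levels)
    w2 = total - w1
    mu1 = np.where(w1 > 0, m1 / np.maximum(w1, 1e-300), 0.0)
    mu2 = np.where(w2 > 0, (m1[-1] - m1) / np.maximum(w2, 1e-300), 0.0)
    variance = (w1 / total) * (w2 / total) * (mu1 - mu2) ** 2
    variance[w2 == 0] = 0.0
    variance[w1 == 0] = 0.0
    return int(np.argmax(variance))  # argmax takes the first (smallest) maximizer


@dataclass(frozen=True)
class PhenotypeRecord:
    plant_id: str
    height_px: int
    crown_width_px: int
    scale: float  # cm per pixel
    crown_area: float  # cm^2
    stem_fraction: float
    leaf_fraction: float

    def as_dict(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "height_px": self.height_px,
            "crown_width_px": self.crown_width_px,
            "scale_cm_per_px": self.scale,
            "crown_area_cm2": self.crown_area,
            "stem_fraction": self.stem_fraction,
            "leaf_fraction": self.leaf_fraction,
        }


def crown_area(
    mask: np.ndarray, scale: float, plant_id: str = "", height_on: str = "plant"
) -> PhenotypeRecord:
    """Crown area = 1/2 * (height_px * scale) * (crown_width_px * scale).

    Height is the vertical extent of stem+leaf pixels (``height_on="plant"``,
    the default) or of leaf pixels only (``height_on="leaf"``); crown width
    is the horizontal extent of leaf pixels.
    """
    mask = np.asarray(mask)
    if scale <= 0:
        raise ValueError("scale must be positive (cm per pixel)")
    plant = mask > 0
    if not plant.any():
        raise ValueError("mask contains no foreground pixels")
    height_src = plant if height_on == "plant" else mask == LEAF
    rows = np.nonzero(height_src.any(axis=1))[0]
    leaf_cols = np.nonzero((mask == LEAF).any(axis=0))[0]
    height_px = int(rows[-1] - rows[0] + 1) if rows.size else 0
    width_px = int(leaf_cols[-1] - leaf_cols[0] + 1) if leaf_cols.size else 0
    area = 0.5 * (height_px * scale) * (width_px * scale)
    frac = class_proportions(mask)
    return PhenotypeRecord(
        plant_id=plant_id,
        height_px=height_px,
        crown_width_px=width_px,
        scale=float(scale),
        crown_area=float(area),
        stem_fraction=frac[STEM],
        leaf_fraction=frac[LEAF],
    )


def class_proportions(mask: np.ndarray, whole: float | None = None) -> tuple:
    """(background, stem, leaf) pixel fractions; they sum to 1.

    With ``whole`` set (e.g. 10), the tuple is rescaled so its sum equals
    ``whole`` — the stacked-bar convention used for reporting.
    """
    mask = np.asarray(mask)
    n = mask.size
    fr = tuple(float((mask == c).sum()) / n for c in (0, STEM, LEAF))
    if whole is not None:
        fr = tuple(v * whole for v in fr)
    return fr


def fit_predicted_vs_actual(pred, actual) -> tuple[float, float, float]:
    """Ordinary least squares of actual on predicted: (slope, intercept, R^2)."""
    pred = np.asarray(pred, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise ValueError("pred and actual must be 1-D and equally long")
    if pred.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(pred) == 0:
        raise ValueError("zero variance in predicted values")
    slope, intercept = np.polyfit(pred, actual, 1)
    fitted = slope * pred + intercept
    ss_res = float(((actual - fitted) ** 2).sum())
    ss_tot = float(((actual - actual.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)
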