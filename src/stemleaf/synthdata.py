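"""Seeded generator of synthetic plant scenes (RGB image + class mask).

Scenes mimic the structure of seedling photographs taken against a dark
backdrop: thin stems rooted at the bottom border (class 1), elliptical
leaf blobs attached to the stems (class 2), dark background (class 0).
Colours are drawn inside configurable HSV bands (leaves inside the
"green" table range, background inside the "black" range, stems in a
brownish/orange band), with optional impulse noise applied to the image
only.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor
from skimage import draw as skdraw

__all__ = [
    "SceneParams",
    "generate_dataset",
    "generate_scene",
    "load_dataset",
    "read_mask",
    "save_mask",
    "MASK_PALETTE",
]

# paletted-PNG rendering of class masks: background black, stem green, leaf red
MASK_PALETTE = [0, 0, 0, 0, 128, 0, 128, 0, 0]


@dataclass(frozen=True)
class SceneParams:
    """Geometry and colour bands of a generated scene.

    Pixel quantities are expressed at ``size`` = 512 and scaled linearly
    for other image sizes.  HSV bands use H in degrees on the 0-180
    OpenCV scale.
    """

    size: int = 512
    stem_count: tuple[int, int] = (1, 2)
    stem_width: tuple[int, int] = (8, 14)
    leaf_count: tuple[int, int] = (6, 10)
    leaf_major: tuple[int, int] = (60, 110)
    leaf_minor: tuple[int, int] = (28, 55)
    leaf_hue: tuple[int, int] = (40, 70)  # inside the "green" range 35-77
    leaf_sat: tuple[int, int] = (120, 230)
    leaf_val: tuple[int, int] = (90, 220)
    stem_hue: tuple[int, int] = (12, 22)  # brownish-orange
    stem_sat: tuple[int, int] = (120, 220)
    stem_val: tuple[int, int] = (90, 200)
    background_val: tuple[int, int] = (5, 38)  # inside the "black" range V<=46
    noise_density: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("image size must be at least 32 px")
        if not (0.0 <= self.noise_density <= 1.0):
            raise ValueError("noise density must be in [0, 1]")
        for name in ("stem_width", "leaf_major", "leaf_minor"):
            lo, hi = getattr(self, name)
            # ranges are expressed at the 512 px reference scale
            if lo < 1 or hi < lo or self._px(hi) >= self.size // 2:
                raise ValueError(f"{name} range {(lo, hi)} invalid for size {self.size}")

    def _px(self, value: float) -> int:
        return max(1, int(round(value * self.size / 512.0)))

    @classmethod
    def foreground_rich(cls, size: int = 128, seed: int = 0, **overrides) -> "SceneParams":
        """Variant with thick stems and large, numerous leaves (~20-35%
        foreground).  Used for from-scratch training demos, where the
        default background-dominated composition makes the optimisation
        needlessly imbalanced."""
        base = dict(
            size=size,
            seed=seed,
            stem_count=(2, 3),
            stem_width=(14, 22),
            leaf_count=(10, 14),
            leaf_major=(80, 130),
            leaf_minor=(40, 70),
        )
        base.update(overrides)
        return cls(**base)


def _hsv_fill(rng: np.random.Generator, shape, hue, sat, val) -> np.ndarray:
    """Per-pixel jittered HSV inside the given integer bands -> float RGB."""
    h = rng.uniform(hue[0], hue[1], shape) / 180.0
    s = rng.uniform(sat[0], sat[1], shape) / 255.0
    v = rng.uniform(val[0], val[1], shape) / 255.0
    return skcolor.hsv2rgb(np.stack([h, s, v], axis=-1))


def _draw_stem(mask: np.ndarray, rng: np.random.Generator, p: SceneParams) -> np.ndarray:
    """Thickened random-walk polyline rooted at the bottom border.

    Returns the (row, col) vertices so leaves can attach to them.
    """
    size = p.size
    half = max(1, p._px(rng.integers(p.stem_width[0], p.stem_width[1] + 1)) // 2)
    col = int(rng.integers(size // 4, 3 * size // 4))
    row = size - 1
    top = int(rng.integers(int(0.08 * size), int(0.25 * size)))
    points = [(row, col)]
    while row > top:
        step = int(rng.integers(p._px(20), p._px(50) + 1))
        row = max(top, row - step)
        col = int(np.clip(col + rng.integers(-p._px(18), p._px(18) + 1), half, size - 1 - half))
        points.append((row, col))
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc = skdraw.line(r0, c0, r1, c1)
        for dr in range(-half, half + 1):
            for dc in range(-half, half + 1):
                if dr * dr + dc * dc <= half * half:
                    r = np.clip(rr + dr, 0, size - 1)
                    c = np.clip(cc + dc, 0, size - 1)
                    mask[r, c] = 1
    return np.array(points)


def _draw_leaf(mask: np.ndarray, rng: np.random.Generator, p: SceneParams, anchor) -> None:
    size = p.size
    major = p._px(rng.integers(p.leaf_major[0], p.leaf_major[1] + 1)) / 2.0
    minor = p._px(rng.integers(p.leaf_minor[0], p.leaf_minor[1] + 1)) / 2.0
    angle = rng.uniform(0, math.pi)
    dr = rng.integers(-p._px(30), p._px(10) + 1)
    dc = rng.integers(-p._px(60), p._px(60) + 1)
    r0 = int(np.clip(anchor[0] + dr, major, size - 1 - major))
    c0 = int(np.clip(anchor[1] + dc, minor, size - 1 - minor))
    rr, cc = skdraw.ellipse(r0, c0, major, minor, shape=mask.shape, rotation=angle)
    mask[rr, cc] = 2


def generate_scene(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene. Returns (uint8 RGB image, uint8 class mask)."""
    rng = np.random.default_rng(params.seed)
    size = params.size
    mask = np.zeros((size, size), dtype=np.uint8)

    stems = []
    n_stems = int(rng.integers(params.stem_count[0], params.stem_count[1] + 1))
    for _ in range(n_stems):
        stems.append(_draw_stem(mask, rng, params))

    n_leaves = int(rng.integers(params.leaf_count[0], params.leaf_count[1] + 1))
    for _ in range(n_leaves):
        stem = stems[int(rng.integers(len(stems)))]
        upper = stem[stem[:, 0] < 0.75 * size]
        anchor = (upper if len(upper) else stem)[int(rng.integers(len(upper) or len(stem)))]
        _draw_leaf(mask, rng, params, anchor)

    img = _hsv_fill(rng, (size, size), (0, 180), (0, 255), params.background_val)
    stem_px = mask == 1
    leaf_px = mask == 2
    img[stem_px] = _hsv_fill(
        rng, (int(stem_px.sum()),), params.stem_hue, params.stem_sat, params.stem_val
    )
    img[leaf_px] = _hsv_fill(
        rng, (int(leaf_px.sum()),), params.leaf_hue, params.leaf_sat, params.leaf_val
    )
    img = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)

    if params.noise_density > 0:
        noisy = rng.random((size, size)) < params.noise_density
        salt = rng.random((size, size)) < 0.5
        img[noisy & salt] = 255
        img[noisy & ~salt] = 0
    return img, mask


def save_mask(path, mask: np.ndarray) -> None:
    """Write a class mask as a paletted PNG with values 0/1/2."""
    im = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    im.putpalette(MASK_PALETTE + [0] * (768 - len(MASK_PALETTE)))
    im.save(path)


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def generate_dataset(
    n: int,
    params: SceneParams,
    out_dir,
    split_ratio: float = 0.9,
) -> dict:
    """Write images/, masks/, train.txt and val.txt under ``out_dir``.

    The train split size is floor(n * split_ratio); per-scene seeds are
    derived from ``params.seed`` so the tree is reproducible bit-for-bit.
    """
    if n < 2:
        raise ValueError("need at least 2 scenes to split")
    if not (0.0 < split_ratio < 1.0):
        raise ValueError("split ratio must be in (0, 1)")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    names = []
    for i in range(n):
        scene = SceneParams(**{**asdict(params), "seed": params.seed + 1000 * i})
        img, mask = generate_scene(scene)
        name = f"scene_{i:04d}"
        Image.fromarray(img).save(out / "images" / f"{name}.png")
        save_mask(out / "masks" / f"{name}.png", mask)
        names.append(name)

    rng = np.random.default_rng(params.seed)
    order = rng.permutation(n)
    n_train = int(math.floor(n * split_ratio))
    train = sorted(names[i] for i in order[:n_train])
    val = sorted(names[i] for i in order[n_train:])
    (out / "train.txt").write_text("\n".join(train) + "\n")
    (out / "val.txt").write_text("\n".join(val) + "\n")
    manifest = {
        "n": n,
        "split_ratio": split_ratio,
        "n_train": len(train),
        "n_val": len(val),
        "params": asdict(params),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_dataset(data_dir, split: str = "train") -> tuple[np.ndarray, np.ndarray]:
    """Load a generated split as (images float32 [0,1] NHWC, masks uint8 NHW)."""
    data = Path(data_dir)
    list_file = data / f"{split}.txt"
    if not list_file.exists():
        raise FileNotFoundError(f"missing split list {list_file}")
    names = [line for line in list_file.read_text().splitlines() if line.strip()]
    images, masks = [], []
    for name in names:
        img = np.asarray(Image.open(data / "images" / f"{name}.png").convert("RGB"))
        images.append(img.astype(np.float32) / 255.0)
        masks.append(read_mask(data / "masks" / f"{name}.png"))
    return np.stack(images), np.stack(masks)
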