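"""Training objectives: Dice loss, signed-distance Boundary loss, and their
composite.

Conventions (fixed here and used by every worked example in the tests):

* Dice pools the sums over all pixels AND all classes (no per-class
  averaging): ``1 - 2 * sum(g*s) / (sum(g) + sum(s) + eps)``.
* The boundary term is, per foreground class, the spatial MEAN of
  ``phi_G * s`` where ``phi_G`` is the Euclidean signed distance map of the
  ground-truth region (negative strictly inside), averaged over the
  non-degenerate foreground classes.  The mean (rather than sum) makes the
  value resolution-independent.
* Composite = dice + weight * boundary, weight defaulting to 1.

Public functions accept numpy arrays shaped (..., C) channel-last and
return floats; the ``*_t`` variants operate on autograd Tensors shaped
(B, C, H, W) and are used by the training loop.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .nn import Tensor, as_tensor

__all__ = [
    "boundary_loss",
    "boundary_loss_t",
    "dice_boundary_loss",
    "dice_boundary_loss_t",
    "dice_loss",
    "dice_loss_t",
    "distance_maps",
    "one_hot",
    "signed_distance_map",
]

DICE_EPS = 1e-6


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """Integer label raster -> channel-last {0,1} encoding."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ValueError("mask values out of range")
    return np.eye(num_classes, dtype=np.float64)[mask]


def _check_pair(probs: np.ndarray, labels: np.ndarray) -> None:
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {labels.shape}")
    if probs.size == 0:
        raise ValueError("empty input")


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def dice_loss(probs: np.ndarray, labels: np.ndarray, eps: float = DICE_EPS) -> float:
    """Pooled Dice loss in [0, 1]; ``labels`` is one-hot."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    _check_pair(probs, labels)
    inter = float((probs * labels).sum())
    total = float(probs.sum() + labels.sum())
    return 1.0 - 2.0 * inter / (total + eps)


def dice_loss_t(probs: Tensor, labels: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """Autograd Dice on (B, C, H, W) tensors; ``labels`` one-hot ndarray."""
    probs = as_tensor(probs)
    labels = np.asarray(labels, dtype=probs.dtype)
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {labels.shape}")
    inter = (probs * labels).sum()
    total = probs.sum() + float(labels.sum())
    return 1.0 - (2.0 * inter) * ((total + eps) ** -1.0)


# ---------------------------------------------------------------------------
# signed distance maps
# ---------------------------------------------------------------------------


def signed_distance_map(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Euclidean signed distance to the region boundary, negative inside.

    ``|phi|`` at each pixel is the distance to the nearest pixel of the
    opposite value (unit spacing).  For degenerate masks (all background or
    all foreground) there is no boundary: phi is set to +/-1 everywhere and
    the degenerate flag is returned True.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        return np.ones(mask.shape, dtype=np.float64), True
    if mask.all():
        return -np.ones(mask.shape, dtype=np.float64), True
    outside = ndimage.distance_transform_edt(~mask)  # distance to nearest fg
    inside = ndimage.distance_transform_edt(mask)  # distance to nearest bg
    return outside - inside, False


def distance_maps(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """Stack of signed distance maps for the foreground classes 1..C-1.

    Degenerate (absent) classes get a NaN map so downstream reductions can
    skip them.  Shape: (C-1, H, W).
    """
    mask = np.asarray(mask)
    maps = np.empty((num_classes - 1,) + mask.shape, dtype=np.float64)
    for c in range(1, num_classes):
        phi, degenerate = signed_distance_map(mask == c)
        maps[c - 1] = np.nan if degenerate else phi
    return maps


# ---------------------------------------------------------------------------
# Boundary loss
# ---------------------------------------------------------------------------


def boundary_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean of phi_G * s per foreground class, averaged over classes.

    ``labels`` is channel-last one-hot; class 0 is background and is
    excluded.  Classes absent from the ground truth are skipped.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    _check_pair(probs, labels)
    mask = labels.argmax(axis=-1)
    num_classes = probs.shape[-1]
    terms = []
    for c in range(1, num_classes):
        phi, degenerate = signed_distance_map(mask == c)
        if degenerate and not (mask == c).any():
            continue
        terms.append(float((phi * probs[..., c]).mean()))
    return float(np.mean(terms)) if terms else 0.0


def boundary_loss_t(probs: Tensor, phi: np.ndarray) -> Tensor:
    """Autograd boundary term on (B, C, H, W) probs.

    ``phi`` is the precomputed (B, C-1, H, W) stack from
    :func:`distance_maps` (NaN planes mark absent classes and are skipped).
    """
    probs = as_tensor(probs)
    nclasses = probs.shape[1]
    keep = ~np.isnan(phi.reshape(phi.shape[0], phi.shape[1], -1)).any(axis=-1)
    phi_clean = np.where(np.isnan(phi), 0.0, phi).astype(probs.dtype)
    weighted = probs[:, 1:nclasses] * phi_clean
    per_class = weighted.mean(axis=(2, 3))  # (B, C-1)
    w = keep.astype(probs.dtype)
    denom = max(float(w.sum()), 1.0)
    return (per_class * w).sum() * (1.0 / denom)


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------


def dice_boundary_loss(
    probs: np.ndarray, labels: np.ndarray, weight: float = 1.0
) -> float:
    """``dice + weight * boundary`` with weight defaulting to 1."""
    if weight < 0:
        raise ValueError("boundary weight must be non-negative")
    return dice_loss(probs, labels) + weight * boundary_loss(probs, labels)


def dice_boundary_loss_t(
    probs: Tensor, labels: np.ndarray, phi: np.ndarray, weight: float = 1.0
) -> Tensor:
    if weight < 0:
        raise ValueError("boundary weight must be non-negative")
    return dice_loss_t(probs, labels) + weight * boundary_loss_t(probs, phi)
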