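"""Receptive-field arithmetic and gridding-effect validation for stacked
dilated (atrous) convolutions.

A stack of stride-1 dilated convolutions with kernel size ``k`` and rates
``r_1..r_n`` can leave holes in its combined footprint (the "gridding" or
"lattice" effect).  Two validation routes are provided:

* the design rule based on the maximum-distance recursion
  ``M_i = max(M_{i+1} - 2 r_i, M_{i+1} - 2 (M_{i+1} - r_i), r_i)`` with
  ``M_n = r_n``, requiring ``M_2 <= k`` plus coprime rates, and
* a brute-force coverage oracle that materialises the stacked footprint on
  a 1-D grid and checks it for interior holes.

The design rule is order-sensitive and conservative; the coverage oracle
is exact.  They agree on the classic worked schedules but not on every
arbitrary schedule (see :func:`footprint_has_holes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd

import numpy as np

__all__ = [
    "DilationSchedule",
    "build_schedule",
    "dilated_kernel_size",
    "footprint_has_holes",
    "max_nonzero_distances",
    "stacked_footprint",
    "validate_rates",
]

VALID = "valid"
GRIDDING = "gridding"
COMMON_FACTOR = "common_factor"


def _check_kernel(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {k!r}")


def _check_rates(rates) -> list[int]:
    rates = list(rates)
    if not rates:
        raise ValueError("rates must be non-empty")
    for r in rates:
        if not isinstance(r, (int, np.integer)) or r < 1:
            raise ValueError(f"rates must be positive integers, got {rates!r}")
    return [int(r) for r in rates]


def dilated_kernel_size(k: int, r: int) -> int:
    """Effective side length of a k x k kernel dilated at rate r:
    ``kd = k + (k - 1) * (r - 1)``."""
    _check_kernel(k)
    if not isinstance(r, (int, np.integer)) or r < 1:
        raise ValueError(f"dilation rate must be a positive integer, got {r!r}")
    return int(k + (k - 1) * (r - 1))


def max_nonzero_distances(k: int, rates) -> list[int]:
    """Backward recursion for the maximum distance between nonzero taps.

    ``M_n = r_n`` and
    ``M_i = max(M_{i+1} - 2 r_i, M_{i+1} - 2 (M_{i+1} - r_i), r_i)``.
    Returns ``[M_1, ..., M_n]``.
    """
    _check_kernel(k)
    rates = _check_rates(rates)
    n = len(rates)
    m = [0] * n
    m[n - 1] = rates[n - 1]
    for i in range(n - 2, -1, -1):
        nxt = m[i + 1]
        r = rates[i]
        m[i] = max(nxt - 2 * r, nxt - 2 * (nxt - r), r)
    return m


def validate_rates(k: int, rates) -> str:
    """Classify a dilation schedule as ``valid``, ``gridding`` or
    ``common_factor``.

    The common-factor rule fires when gcd(rates) > 1; otherwise the
    schedule is invalid ("gridding") when M_2 > k.
    """
    rates = _check_rates(rates)
    _check_kernel(k)
    if gcd(*rates) > 1:
        return COMMON_FACTOR
    m = max_nonzero_distances(k, rates)
    if len(m) >= 2 and m[1] > k:
        return GRIDDING
    return VALID


@dataclass(frozen=True)
class DilationSchedule:
    """A kernel size, its ordered dilation rates, the M_i recursion values
    and the resulting validity verdict."""

    kernel_size: int
    rates: tuple[int, ...]
    max_distances: tuple[int, ...] = field(default=())
    verdict: str = VALID

    @property
    def valid(self) -> bool:
        return self.verdict == VALID


def build_schedule(k: int, rates) -> DilationSchedule:
    rates = tuple(_check_rates(rates))
    return DilationSchedule(
        kernel_size=int(k),
        rates=rates,
        max_distances=tuple(max_nonzero_distances(k, rates)),
        verdict=validate_rates(k, rates),
    )


# ---------------------------------------------------------------------------
# brute-force coverage oracle
# ---------------------------------------------------------------------------


def stacked_footprint(k: int, rates) -> np.ndarray:
    """1-D offsets covered by the composition of the dilated kernels.

    The composed filter's support is the Minkowski sum of the individual
    tap sets ``{j * r_i : j = -(k-1)/2 .. (k-1)/2}``.  Returned as a sorted
    integer array of offsets.
    """
    _check_kernel(k)
    rates = _check_rates(rates)
    m = (k - 1) // 2
    half = m * sum(rates)
    size = 2 * half + 1
    cover = np.zeros(size, dtype=bool)
    cover[half] = True
    for r in rates:
        taps = np.zeros(size, dtype=bool)
        for j in range(-m, m + 1):
            taps[half + j * r] = True
        cover = np.convolve(cover, taps)[half : half + size] > 0
    return np.nonzero(cover)[0] - half


def footprint_has_holes(k: int, rates) -> bool:
    """True when the stacked footprint has interior holes (gridding).

    This is the exact, order-invariant coverage check; the ``M_2 <= k`` +
    coprimality design rule is a conservative, order-sensitive
    approximation of it.
    """
    offsets = stacked_footprint(k, rates)
    return bool(np.any(np.diff(offsets) > 1))
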