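"""Hysteresis (double-threshold) binarization with fraction-based thresholds.

A single threshold fails on vessel trees whose thin branches fade into the
noise floor.  Hysteresis keeps every pixel above a high threshold, plus
every pixel above a low threshold that is 8-connected to a high pixel
through other above-low pixels.  Thresholds are not fixed intensities but
are chosen per image so that a given fraction of pixels exceeds them,
making the binarization robust to global intensity shifts; the fractions
are protocol parameters (they track the vessel/background ratio of a
camera setup and field of view).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "HysteresisParams",
    "fraction_to_threshold",
    "seed_noise_floor",
    "hysteresis_threshold",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class HysteresisParams:
    """Pixel fractions for the high (seed) and low (grow) thresholds.

    Roughly 15% of fundus pixels belong to vessels; seeding on the top 2%
    and growing through the top 12% are sane defaults, to be tuned per
    acquisition protocol.
    """

    high_fraction: float | list[float] = 0.02
    low_fraction: float | list[float] = 0.12
    connectivity: int = 8
    seed_floor_factor: float | list[float] = 8.0

    def __post_init__(self) -> None:
        for h, l in zip(np.atleast_1d(self.high_fraction), np.atleast_1d(self.low_fraction)):
            if not 0 < h < l < 1:
                raise ValueError("need 0 < high_fraction < low_fraction < 1")
        if self.connectivity != 8:
            raise ValueError("only 8-connectivity is supported")
        if np.any(np.asarray(self.seed_floor_factor) < 0):
            raise ValueError("seed_floor_factor must be >= 0")

    def at_level(self, k: int) -> "HysteresisParams":
        """Resolve per-level parameter lists to scalars for level ``k``."""
        fields = (self.high_fraction, self.low_fraction, self.seed_floor_factor)
        if all(np.isscalar(f) for f in fields):
            return self

        def pick(f: float | list[float]) -> float:
            if np.isscalar(f):
                return float(f)
            return float(f[min(k, len(f) - 1)])

        return HysteresisParams(
            high_fraction=pick(self.high_fraction),
            low_fraction=pick(self.low_fraction),
            seed_floor_factor=pick(self.seed_floor_factor),
        )


def fraction_to_threshold(v: np.ndarray, fraction: float) -> float:
    """Threshold such that at least ``fraction`` of pixels are >= it.

    This is the (1-fraction) order statistic: with N pixels, the
    ceil(fraction*N)-th largest value.  On a constant map the constant is
    returned (every pixel then passes).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    flat = np.asarray(v, dtype=np.float64).ravel()
    n = flat.size
    k = min(n, max(1, math.ceil(fraction * n)))
    return float(np.partition(flat, n - k)[n - k])


def seed_noise_floor(v: np.ndarray, factor: float) -> float:
    """Absolute floor for the seed threshold: ``factor`` times the median
    positive response.

    On a map dominated by background the median positive response is a
    noise statistic; a genuine vessel seed stands nearly an order of
    magnitude above it, while on a vessel-free map even the strongest
    responses stay within a few multiples of the median.  The floor
    enforces the requirement that no background pixel can reach the seed
    threshold, which the percent-of-pixels rule alone cannot guarantee.
    Compute it on the native-resolution map: interpolation during
    upsampling dilutes the median.
    """
    if factor <= 0:
        return -np.inf
    pos = v[v > 0]
    if pos.size == 0:
        return np.inf
    return factor * float(np.median(pos))


def hysteresis_threshold(
    v: np.ndarray,
    p: HysteresisParams | None = None,
    seed_floor: float | None = None,
    t_high: float | None = None,
    t_low: float | None = None,
) -> np.ndarray:
    """Binarize a vesselness map with fraction-derived double thresholds.

    Returns a {0,1} uint8 mask: all pixels >= t_high, plus pixels >=
    t_low 8-connected to them through pixels >= t_low.  The high mask is
    always a subset of the output, which is a subset of the low mask.

    The seed threshold is additionally clamped from below by an absolute
    noise floor (see :func:`seed_noise_floor`); pass ``seed_floor``
    explicitly when the statistic should come from a different raster
    (e.g. the pre-upsampling pyramid level), or set
    ``p.seed_floor_factor`` to 0 to disable the guard.  Explicit
    ``t_high``/``t_low`` values override the fraction-derived thresholds
    (used when the statistics must come from a different map, e.g. the
    response before reflex correction).
    """
    p = p or HysteresisParams()
    v = np.asarray(v, dtype=np.float64)
    if t_high is None:
        if seed_floor is None:
            seed_floor = seed_noise_floor(v, p.seed_floor_factor)
        t_high = max(fraction_to_threshold(v, p.high_fraction), seed_floor)
    if t_low is None:
        t_low = fraction_to_threshold(v, p.low_fraction)
    low = v >= t_low
    high = v >= t_high
    if not high.any():
        return np.zeros(v.shape, dtype=np.uint8)
    labels, n = ndi.label(low, structure=_STRUCT8)
    if n == 0:
        return np.zeros(v.shape, dtype=np.uint8)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[high])] = True
    keep[0] = False
    return keep[labels].astype(np.uint8)
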