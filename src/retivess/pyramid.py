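"""Halving resolution hierarchy and bilinear upsampling.

Instead of sweeping the filter scale sigma over an image, the pipeline
keeps sigma fixed at 1 and halves the image: a vessel of width w appears
w/2^k pixels wide at level k, so each level makes a different thickness
band detectable with the same small kernel.  Per-level results are resized
back to the input resolution with bilinear interpolation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "choose_levels",
    "max_levels",
    "build_hierarchy",
    "upsample_to",
]

#: vessel width (px) well captured by sigma=1 at full resolution
BASE_WIDTH = 4.0

#: minimum side length of the coarsest pyramid level
MIN_LEVEL_SIDE = 8


def max_levels(shape: tuple[int, int]) -> int:
    """Largest level count keeping the coarsest level at least 8x8."""
    h, w = shape
    k = 0
    while math.ceil(h / 2 ** (k + 1)) >= MIN_LEVEL_SIDE and math.ceil(
        w / 2 ** (k + 1)
    ) >= MIN_LEVEL_SIDE:
        k += 1
    return k + 1


def choose_levels(img_shape: tuple[int, int], max_vessel_width: float) -> int:
    """Level count needed to shrink the thickest vessel to ~sigma=1 scale.

    n = max(2, ceil(log2(max_vessel_width / 4)) + 1), capped so the
    coarsest level stays at least 8x8.  Low-resolution fundus images
    (vessels up to ~8-10 px) get 2-3 levels; high-resolution images with
    vessels up to ~40 px get 5.
    """
    if max_vessel_width < 1:
        raise ValueError("max_vessel_width must be >= 1")
    if max_vessel_width <= BASE_WIDTH:
        n = 2
    else:
        n = max(2, math.ceil(math.log2(max_vessel_width / BASE_WIDTH)) + 1)
    return min(n, max_levels(img_shape))


def build_hierarchy(
    img: np.ndarray,
    n_levels: int,
    sigma_aa: float = 1.0,
    literal_order: bool = False,
) -> list[np.ndarray]:
    """Gaussian pyramid: level 0 is the input, each next level half-sized.

    Each level is derived from the previous by Gaussian anti-alias
    smoothing (sigma_aa) followed by 2x decimation taking every second
    pixel starting at index 0; odd dimensions round up (ceil).  With
    ``literal_order`` the two steps are swapped (decimate, then smooth),
    which aliases and exists only for comparison.
    """
    img = np.asarray(img, dtype=np.float64)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    cap = max_levels(img.shape)
    if n_levels > cap:
        raise ValueError(
            f"n_levels={n_levels} too deep for image {img.shape}; "
            f"at most {cap} levels keep the coarsest level >= 8x8"
        )
    levels = [img]
    for _ in range(1, n_levels):
        prev = levels[-1]
        if literal_order:
            nxt = ndi.gaussian_filter(prev[::2, ::2], sigma_aa, mode="reflect")
        else:
            nxt = ndi.gaussian_filter(prev, sigma_aa, mode="reflect")[::2, ::2]
        levels.append(nxt)
    return levels


def upsample_to(arr: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling to ``target_shape`` (corner-aligned).

    Grid corners map to grid corners: fine coordinate i maps to coarse
    i*(src-1)/(dst-1), which coincides with the start-at-0 decimation grid
    for odd source dimensions.  As a convex combination of source values
    the output never exceeds the source extremes.  Identity shapes return
    a bit-identical copy; downscaling is rejected.
    """
    arr = np.asarray(arr, dtype=np.float64)
    th, tw = target_shape
    sh, sw = arr.shape
    if th < sh or tw < sw:
        raise ValueError(f"upsample_to cannot shrink {arr.shape} -> {target_shape}")
    if (th, tw) == (sh, sw):
        return arr.copy()
    ys = np.linspace(0.0, sh - 1.0, th) if th > 1 else np.zeros(1)
    xs = np.linspace(0.0, sw - 1.0, tw) if tw > 1 else np.zeros(1)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndi.map_coordinates(arr, [yy, xx], order=1, mode="nearest")
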