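"""Mask fusion and morphological cleanup of the segmentation.

Per-level binary masks are fused by pixelwise OR (a vessel found at any
resolution survives).  Coarse levels oversegment thin vessels after
upsampling, so the fused mask is thinned back to the strongest intensity
gradient, then smoothed by a small morphological closing; finally small
spurious objects are removed and small holes in the vessel tree filled.

Foreground uses 8-connectivity and background 4-connectivity throughout,
the standard pairing that avoids topological paradoxes on a square grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "PostprocessParams",
    "fuse_or",
    "sobel_magnitude",
    "thin_to_gradient",
    "morph_close",
    "clean_objects",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndi.generate_binary_structure(2, 1)

# ring of 8 neighbor offsets around a center pixel
_RING = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


@dataclass
class PostprocessParams:
    """Cleanup thresholds at full (reference 565-px-wide) resolution.

    Object/hole sizes scale quadratically with image width relative to the
    reference, so one setting transfers across resolutions.  ``enabled``
    False bypasses thinning, closing and size cleanup entirely (used by
    robustness studies).
    """

    thinning: bool = True
    min_object_px: int = 50
    max_hole_px: int = 50
    closing_size: int = 3
    reference_width: int = 565
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.min_object_px < 0 or self.max_hole_px < 0:
            raise ValueError("size thresholds must be >= 0")
        if self.closing_size < 1:
            raise ValueError("closing_size must be >= 1")

    def scaled_sizes(self, width: int) -> tuple[int, int]:
        f = (width / self.reference_width) ** 2
        return round(self.min_object_px * f), round(self.max_hole_px * f)


def fuse_or(masks: list[np.ndarray]) -> np.ndarray:
    """Pixelwise union of binary masks of identical shape."""
    if not masks:
        raise ValueError("fuse_or needs at least one mask")
    shape = np.asarray(masks[0]).shape
    acc = np.zeros(shape, dtype=bool)
    for m in masks:
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError(f"mask shape {m.shape} != {shape}")
        acc |= m.astype(bool)
    return acc.astype(np.uint8)


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude (used only for ordering comparisons)."""
    img = np.asarray(img, dtype=np.float64)
    gx = ndi.sobel(img, axis=1, mode="reflect")
    gy = ndi.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def _removal_table() -> np.ndarray:
    """256-entry lookup: may a pixel with this 8-neighborhood be removed?

    Neighborhood bits follow _RING order.  Removal is allowed when the
    foreground neighbors form exactly one 8-connected component within
    the 3x3 ring, so removing the pixel cannot split its component;
    isolated pixels (no neighbors) are not removable.
    """
    adj = [
        [
            j
            for j in range(8)
            if j != i
            and max(abs(_RING[i][0] - _RING[j][0]), abs(_RING[i][1] - _RING[j][1])) == 1
        ]
        for i in range(8)
    ]
    table = np.zeros(256, dtype=bool)
    for mask in range(256):
        bits = [i for i in range(8) if mask >> i & 1]
        if len(bits) == 0:
            continue
        if len(bits) == 1:
            table[mask] = True
            continue
        seen = {bits[0]}
        stack = [bits[0]]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if mask >> j & 1 and j not in seen:
                    seen.add(j)
                    stack.append(j)
        table[mask] = len(seen) == len(bits)
    return table


_REMOVABLE = _removal_table()


def _shifted(arr: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Array shifted so out[y, x] = arr[y+dy, x+dx], padded with ``fill``."""
    h, w = arr.shape
    out = np.full_like(arr, fill)
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = arr[max(0, dy) : h + min(0, dy), max(0, dx) : w + min(0, dx)]
    return out


def _directional_max(grad: np.ndarray, lookahead: int) -> dict[tuple[int, int], np.ndarray]:
    """For each of the 8 directions d: max gradient over the next
    ``lookahead`` pixels along d (excluding the pixel itself), computed by
    doubling shifted maxima."""
    out = {}
    for dy, dx in _RING:
        m = _shifted(grad, dy, dx, -np.inf)
        step = 1
        while step < lookahead:
            m = np.maximum(m, _shifted(m, dy * step, dx * step, -np.inf))
            step *= 2
        out[(dy, dx)] = m
    return out


def thin_to_gradient(
    mask: np.ndarray,
    img: np.ndarray,
    max_iter: int | None = None,
    lookahead: int = 32,
    ridge_strength: float = 0.5,
) -> np.ndarray:
    """Erode a mask inward until its boundary rests on the gradient ridge.

    ``img`` is the preprocessed green channel at full resolution.  Each
    pass removes boundary pixels that have not yet reached the highest
    local gradient along the inward normal: a pixel goes when some pixel
    within ``lookahead`` steps along the inward direction (quantized to 8
    directions) has a strictly larger Sobel gradient magnitude.  A
    boundary pixel already sitting on the gradient ridge -- no stronger
    gradient further inward -- stays, so masks bounded by intensity edges
    are fixed points.  Pixels whose removal would split their 8-connected
    component are never removed, so the component count cannot increase;
    interior holes do not erode (they are artifacts of per-level
    thresholding and are handled by the cleanup stage).  Removal within
    a pass is sequential in raster order, which keeps the connectivity
    guard exact and the result deterministic.
    """
    m = np.asarray(mask).astype(bool).copy()
    img = np.asarray(img, dtype=np.float64)
    if m.shape != img.shape:
        raise ValueError(f"mask {m.shape} and image {img.shape} shapes differ")
    grad = sobel_magnitude(img)
    h, w = m.shape
    if max_iter is None:
        max_iter = max(h, w)
    dirmax = _directional_max(grad, lookahead)

    for _ in range(max_iter):
        # erode only from the outer boundary: interior holes (filled later
        # by the cleanup stage) must not hollow the vessel from within
        bg_labels, nbg = ndi.label(~m, structure=_STRUCT4)
        if nbg == 0:
            break
        is_outside = np.zeros(nbg + 1, dtype=bool)
        for sl in (bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]):
            is_outside[np.unique(sl)] = True
        is_outside[0] = False
        outside = is_outside[bg_labels]
        by, bx = np.nonzero(m & ndi.binary_dilation(outside, structure=_STRUCT8))
        if by.size == 0:
            break
        # inward normal ~ opposite of the mean outside-neighbor offset
        padded = np.pad(outside, 1).astype(np.int8)
        ny = np.zeros(by.size, dtype=np.int64)
        nx = np.zeros(by.size, dtype=np.int64)
        for dy, dx in _RING:
            bg = padded[by + 1 + dy, bx + 1 + dx]
            ny -= dy * bg
            nx -= dx * bg
        sy = np.sign(ny)
        sx = np.sign(nx)
        qy = (by + sy).clip(0, h - 1)
        qx = (bx + sx).clip(0, w - 1)
        valid = ((sy != 0) | (sx != 0)) & m[qy, qx]
        # not yet at the gradient ridge: something stronger lies inward
        ahead = np.full(by.size, -np.inf)
        for d, dm in dirmax.items():
            sel = (sy == d[0]) & (sx == d[1])
            if sel.any():
                ahead[sel] = dm[by[sel], bx[sel]]
        g0 = grad[by, bx]
        valid &= ahead > g0
        # a pixel sitting on a local gradient maximum along the normal is
        # already at an edge ridge and must not erode through it
        oy = (by - sy).clip(0, h - 1)
        ox = (bx - sx).clip(0, w - 1)
        local_max = (g0 >= grad[qy, qx]) & (g0 >= grad[oy, ox])
        ridge = local_max & (g0 >= ridge_strength * ahead)
        valid &= ~ridge
        cy, cx = by[valid], bx[valid]
        removed = 0
        for y, x in zip(cy.tolist(), cx.tolist()):
            code = 0
            for i, (dy, dx) in enumerate(_RING):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and m[yy, xx]:
                    code |= 1 << i
            if _REMOVABLE[code]:
                m[y, x] = False
                removed += 1
        if removed == 0:
            break
    return m.astype(np.uint8)


def morph_close(mask: np.ndarray, size: int = 3) -> np.ndarray:
    """Morphological closing with a square structuring element.

    The mask is padded with background before closing, so the operation
    behaves as on an infinite plane: it is extensive (output contains the
    input) and idempotent.
    """
    m = np.asarray(mask).astype(bool)
    pad = size
    padded = np.pad(m, pad)
    closed = ndi.binary_closing(padded, structure=np.ones((size, size), dtype=bool))
    return closed[pad:-pad, pad:-pad].astype(np.uint8)


def clean_objects(mask: np.ndarray, min_object_px: int, max_hole_px: int) -> np.ndarray:
    """Remove small foreground objects and fill small enclosed holes.

    8-connected foreground components with fewer than ``min_object_px``
    pixels are dropped; 4-connected background components that do not
    touch the frame border and have fewer than ``max_hole_px`` pixels are
    filled.  Thresholds of 0 make this the identity.
    """
    m = np.asarray(mask).astype(bool)
    if min_object_px > 0:
        labels, n = ndi.label(m, structure=_STRUCT8)
        if n:
            sizes = np.bincount(labels.ravel(), minlength=n + 1)
            keep = sizes >= min_object_px
            keep[0] = False
            m = keep[labels]
    if max_hole_px > 0:
        labels, n = ndi.label(~m, structure=_STRUCT4)
        if n:
            border = np.zeros(n + 1, dtype=bool)
            for sl in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
                border[np.unique(sl)] = True
            sizes = np.bincount(labels.ravel(), minlength=n + 1)
            fill = ~border & (sizes < max_hole_px)
            fill[0] = False
            m = m | fill[labels]
    return m.astype(np.uint8)
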