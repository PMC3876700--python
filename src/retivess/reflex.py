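"""Specular (central) reflex correction on coarse-level vesselness maps.

The camera flash can leave a bright stripe along the centerline of thick
vessels.  Ridge filters then respond with a dip exactly where the vessel is
widest.  At the coarsest pyramid level -- where only thick vessels survive
-- such a dip is recognizable in a 3x3 neighborhood: the center pixel is
weaker than two opposite neighbors in the vesselness map yet *brighter*
than the same two neighbors in the intensity image (reflex = bright).  The
center is then filled with the mean of the two neighbors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["correct_specular_reflex"]

# the four opposite-direction neighbor pairs of a 3x3 neighborhood
_PAIRS = (
    ((-1, 0), (1, 0)),  # N-S
    ((0, -1), (0, 1)),  # W-E
    ((-1, -1), (1, 1)),  # NW-SE
    ((-1, 1), (1, -1)),  # NE-SW
)


def correct_specular_reflex(v: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Fill reflex dips in a vesselness map, guided by the intensity image.

    ``intensity`` is the (non-inverted) green-channel image of the same
    pyramid level, so the reflex shows as a local brightness maximum.  A
    single pass reads only from the input map; when several neighbor pairs
    qualify, the pair giving the largest replacement wins.  The output is
    pixelwise >= the input and border pixels are left unchanged.
    """
    v = np.asarray(v, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if v.shape != intensity.shape:
        raise ValueError(
            f"vesselness {v.shape} and intensity {intensity.shape} shapes differ"
        )
    out = v.copy()
    if min(v.shape) < 3:
        return out
    h, w = v.shape
    cv = v[1:-1, 1:-1]
    ci = intensity[1:-1, 1:-1]
    best = np.full(cv.shape, -np.inf)
    hit = np.zeros(cv.shape, dtype=bool)
    for (dy1, dx1), (dy2, dx2) in _PAIRS:
        va = v[1 + dy1 : h - 1 + dy1, 1 + dx1 : w - 1 + dx1]
        vb = v[1 + dy2 : h - 1 + dy2, 1 + dx2 : w - 1 + dx2]
        ia = intensity[1 + dy1 : h - 1 + dy1, 1 + dx1 : w - 1 + dx1]
        ib = intensity[1 + dy2 : h - 1 + dy2, 1 + dx2 : w - 1 + dx2]
        cond = (cv < va) & (cv < vb) & (ci > ia) & (ci > ib)
        cand = 0.5 * (va + vb)
        best = np.where(cond & (cand > best), cand, best)
        hit |= cond
    out[1:-1, 1:-1] = np.where(hit, best, cv)
    return out
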