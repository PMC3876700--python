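"""Single-scale Hessian vesselness and a classical multiscale reference.

The vesselness measure scores every pixel for tubular (ridge-like) local
structure from the eigenvalues ``lambda1, lambda2`` (ordered by magnitude,
``|lambda1| <= |lambda2|``) of the scale-normalized Hessian:

    R_B = lambda1 / lambda2          (blobness: ~0 on lines, ~1 on blobs)
    S   = sqrt(lambda1^2 + lambda2^2)  (structuredness: ~0 on flat noise)

    V0 = 0                                       if lambda2 > 0
       = exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2))   otherwise

for bright ridges on a dark background; dark vessels are handled upstream
by inverting the input.  Second derivatives are computed by separable
convolution with sampled Gaussian-derivative kernels and multiplied by
``sigma^2`` (gamma-normalization) so responses are comparable across scales.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "FrangiParams",
    "HessianField",
    "EigenPair",
    "VesselnessMap",
    "gaussian_derivative_kernel",
    "hessian_at_scale",
    "eigenvalues_sym2x2",
    "vesselness",
    "multiscale_frangi_reference",
]

log = logging.getLogger(__name__)

#: kernels are truncated at this many standard deviations
KERNEL_TRUNCATE = 4.0


@dataclass
class FrangiParams:
    """Sensitivity constants of the vesselness measure.

    beta controls suppression of blob-like structures; c separates real
    structure from flat background noise.  c="auto" resolves to half the
    maximum structuredness S of the field being scored, a standard
    heuristic that adapts to image contrast.  ``polarity`` records whether
    vessels are dark (fundus green channel) or bright in the input.
    """

    sigma: float = 1.0
    beta: float = 0.5
    c: float | str = "auto"
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if isinstance(self.c, str):
            if self.c != "auto":
                raise ValueError("c must be a positive number or 'auto'")
        elif self.c <= 0:
            raise ValueError("c must be a positive number or 'auto'")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


@dataclass
class HessianField:
    """Scale-normalized second-order Gaussian derivatives at one scale."""

    hxx: np.ndarray
    hxy: np.ndarray
    hyy: np.ndarray
    sigma: float = 1.0


@dataclass
class EigenPair:
    """Hessian eigenvalues ordered by magnitude, |lambda1| <= |lambda2|."""

    lambda1: np.ndarray
    lambda2: np.ndarray


@dataclass
class VesselnessMap:
    """Per-pixel vesselness V0 in [0,1), with optional diagnostics."""

    v0: np.ndarray
    level_index: int = 0
    r_b: np.ndarray | None = field(default=None, repr=False)
    s_norm: np.ndarray | None = field(default=None, repr=False)


def gaussian_derivative_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled derivative-of-Gaussian kernel, truncated at 4 sigma.

    order 0: g(x) = exp(-x^2/2s^2) / (sqrt(2 pi) s)
    order 1: g'(x) = -x/s^2 * g(x)
    order 2: g''(x) = (x^2 - s^2)/s^4 * g(x)

    The sampled second-derivative kernel is re-centered to sum exactly to
    zero, so a constant image has an exactly zero Hessian despite the
    finite truncation (the first-derivative kernel is antisymmetric and
    sums to zero by construction).
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    radius = int(math.ceil(KERNEL_TRUNCATE * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2)) / (math.sqrt(2.0 * math.pi) * sigma)
    if order == 0:
        return g
    if order == 1:
        return -x / sigma**2 * g
    g2 = (x**2 - sigma**2) / sigma**4 * g
    return g2 - g2.sum() / g2.size


def hessian_at_scale(img: np.ndarray, sigma: float) -> HessianField:
    """Hessian of an image by Gaussian-derivative convolution at one scale.

    Returns gamma-normalized derivatives (multiplied by sigma^2) computed
    with separable correlation and reflect border handling.  ``x`` is the
    column axis (axis 1), ``y`` the row axis (axis 0).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(img, dtype=np.float64)
    radius = int(math.ceil(KERNEL_TRUNCATE * sigma))
    if min(img.shape) < 2 * radius + 1:
        raise ValueError(
            f"image {img.shape} smaller than derivative kernel support "
            f"({2 * radius + 1} px at sigma={sigma})"
        )
    g0 = gaussian_derivative_kernel(sigma, 0)
    g1 = gaussian_derivative_kernel(sigma, 1)
    g2 = gaussian_derivative_kernel(sigma, 2)
    norm = sigma**2

    def sep(kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
        tmp = ndi.correlate1d(img, kx, axis=1, mode="reflect")
        return ndi.correlate1d(tmp, ky, axis=0, mode="reflect")

    hxx = norm * sep(g2, g0)
    hyy = norm * sep(g0, g2)
    hxy = norm * sep(g1, g1)
    return HessianField(hxx=hxx, hxy=hxy, hyy=hyy, sigma=sigma)


def eigenvalues_sym2x2(h: HessianField) -> EigenPair:
    """Closed-form eigenvalues of the symmetric 2x2 Hessian per pixel.

    m +- sqrt(d^2 + hxy^2) with m = (hxx+hyy)/2, d = (hxx-hyy)/2, assigned
    so that |lambda1| <= |lambda2|; an exact magnitude tie takes lambda2 as
    the more negative value, which favors ridge detection.
    """
    m = 0.5 * (h.hxx + h.hyy)
    d = 0.5 * (h.hxx - h.hyy)
    r = np.sqrt(d * d + h.hxy * h.hxy)
    a = m + r
    b = m - r
    # b is the more negative root, so |a| <= |b| (including exact ties)
    # already picks the tie-break we want: lambda2 = b.
    a_larger = np.abs(a) > np.abs(b)
    lam2 = np.where(a_larger, a, b)
    lam1 = np.where(a_larger, b, a)
    return EigenPair(lambda1=lam1, lambda2=lam2)


def vesselness(
    e: EigenPair,
    p: FrangiParams | None = None,
    level_index: int = 0,
    keep_diagnostics: bool = False,
) -> VesselnessMap:
    """Vesselness V0 from an eigenvalue field (bright-ridge convention).

    Pixels with lambda2 >= 0 score exactly 0: a bright ridge requires
    strong negative curvature across it.  With ``c='auto'`` the
    structuredness constant resolves to half the maximum S over this
    field; if the field is identically zero the map is all zeros.
    """
    p = p or FrangiParams()
    lam1 = np.asarray(e.lambda1, dtype=np.float64)
    lam2 = np.asarray(e.lambda2, dtype=np.float64)
    s2 = lam1 * lam1 + lam2 * lam2
    ridge = lam2 < 0
    if isinstance(p.c, str):  # "auto"
        s_max = math.sqrt(float(s2.max())) if s2.size else 0.0
        if s_max == 0.0:
            log.warning("vesselness: zero eigenvalue field, cannot resolve c='auto'")
            zeros = np.zeros_like(lam1)
            return VesselnessMap(v0=zeros, level_index=level_index)
        c = 0.5 * s_max
    else:
        c = float(p.c)
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = np.where(ridge, lam1 / np.where(ridge, lam2, 1.0), 0.0)
    v0 = np.exp(-(rb * rb) / (2.0 * p.beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c * c)))
    v0 = np.where(ridge, v0, 0.0)
    out = VesselnessMap(v0=v0, level_index=level_index)
    if keep_diagnostics:
        out.r_b = np.where(ridge, rb, np.nan)
        out.s_norm = np.sqrt(s2)
    return out


def multiscale_frangi_reference(
    img: np.ndarray,
    sigma_min: float,
    sigma_max: float,
    sigma_step: float = 1.0,
    p: FrangiParams | None = None,
) -> VesselnessMap:
    """Classical multiscale vesselness: maximum response over a sigma sweep.

    Runs the single-scale filter for sigma from ``sigma_min`` to
    ``sigma_max`` (inclusive, step ``sigma_step``) and combines by
    pixelwise maximum; the sigma^2 normalization of the derivatives is
    the weighting that makes responses across scales comparable.  This is
    the comparison backend; the pyramid backend replaces the sweep with a
    resolution hierarchy at fixed sigma.
    """
    p = p or FrangiParams()
    if sigma_min > sigma_max:
        raise ValueError("sigma_min must be <= sigma_max")
    if sigma_step <= 0:
        raise ValueError("sigma_step must be positive")
    sigmas = np.arange(sigma_min, sigma_max + 0.5 * sigma_step, sigma_step)
    if sigmas.size == 0:
        raise ValueError("empty scale range")
    img = np.asarray(img, dtype=np.float64)
    best = np.zeros_like(img)
    for s in sigmas:
        v = vesselness(eigenvalues_sym2x2(hessian_at_scale(img, float(s))), p)
        np.maximum(best, v.v0, out=best)
    return VesselnessMap(v0=best, level_index=-1)
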