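"""Green-channel extraction and contrast/noise conditioning.

Of the three color channels of a fundus photograph the green channel has the
best vessel/background contrast (red tends to saturate, blue is
under-illuminated), so all further processing works on it.  Contrast is
boosted by percentile-based histogram stretching and background texture is
suppressed by edge-preserving bilateral denoising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_bilateral as _sk_bilateral

from .types import FundusImage

__all__ = [
    "PreprocessParams",
    "extract_green",
    "stretch_histogram",
    "denoise_bilateral",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Knobs for histogram stretching and bilateral denoising.

    Percentiles (1, 99) are robust against specular outliers; a spatial
    sigma of 3 px and a range sigma of 0.1 (on the [0,1] scale) smooth
    background texture while preserving vessel edges, which are typically
    0.1-0.3 deep in normalized intensity.
    """

    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0
    bilateral_sigma_spatial: float = 3.0
    bilateral_sigma_range: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.stretch_low_pct < 50:
            raise ValueError("stretch_low_pct must be in [0, 50)")
        if not 50 < self.stretch_high_pct <= 100:
            raise ValueError("stretch_high_pct must be in (50, 100]")
        if self.bilateral_sigma_spatial <= 0 or self.bilateral_sigma_range <= 0:
            raise ValueError("bilateral sigmas must be positive")


def extract_green(img: FundusImage) -> np.ndarray:
    """Green channel normalized to [0,1] by the format's white level."""
    return img.pixels[:, :, 1].astype(np.float64) / img.white_level


def stretch_histogram(img: np.ndarray, p: PreprocessParams | None = None) -> np.ndarray:
    """Linear contrast stretch between two intensity percentiles.

    Values at/below the low percentile map to 0, at/above the high
    percentile to 1, linearly in between; the map is monotone
    non-decreasing.  A constant image is returned unchanged (with a
    warning), since no stretch is defined.
    """
    p = p or PreprocessParams()
    img = np.asarray(img, dtype=np.float64)
    lo = np.percentile(img, p.stretch_low_pct)
    hi = np.percentile(img, p.stretch_high_pct)
    if hi <= lo:
        log.warning("histogram stretch skipped: constant image (value %g)", lo)
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def denoise_bilateral(img: np.ndarray, p: PreprocessParams | None = None) -> np.ndarray:
    """Edge-preserving bilateral smoothing on a [0,1] gray image."""
    p = p or PreprocessParams()
    img = np.asarray(img, dtype=np.float64)
    out = _sk_bilateral(
        img,
        sigma_color=p.bilateral_sigma_range,
        sigma_spatial=p.bilateral_sigma_spatial,
    )
    return np.clip(out, 0.0, 1.0)


def preprocess(img: FundusImage, p: PreprocessParams | None = None) -> np.ndarray:
    """Full conditioning chain: green channel -> stretch -> bilateral.

    With ``p.enabled`` False only the normalized green channel is returned;
    this is the knob used by robustness studies that skip preprocessing.
    """
    p = p or PreprocessParams()
    g = extract_green(img)
    if not p.enabled:
        return g
    return denoise_bilateral(stretch_histogram(g, p), p)
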