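"""Core raster types shared across the segmentation pipeline.

Arrays follow the raster convention throughout the package: row-major,
origin at the top-left corner, 0-based pixel indices.  ``x`` denotes the
column axis (axis 1) and ``y`` the row axis (axis 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FundusImage", "format_max"]


def format_max(dtype: np.dtype) -> float:
    """Nominal white level of a raster dtype (255 for uint8, 1.0 for floats)."""
    dtype = np.dtype(dtype)
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 1.0


@dataclass
class FundusImage:
    """A 3-channel (RGB) color fundus photograph.

    ``pixels`` keeps the decoded dtype (8- or 16-bit) untouched; intensity
    normalization happens only when a working gray channel is extracted.
    """

    pixels: np.ndarray
    source_path: str = field(default="<memory>")

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(
                f"FundusImage requires an HxWx3 raster, got shape {p.shape}"
            )
        if p.shape[0] < 16 or p.shape[1] < 16:
            raise ValueError(f"image too small: {p.shape[0]}x{p.shape[1]} (minimum 16x16)")
        if np.issubdtype(p.dtype, np.floating) and p.min() < 0:
            raise ValueError("negative pixel values in fundus image")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def white_level(self) -> float:
        return format_max(self.pixels.dtype)
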