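"""Image and mask I/O plus convenience globbing for common dataset layouts.

Masks are exchanged as {0,1} uint8 arrays in memory and written as 8-bit
single-channel PNG with vessel=255, background=0.  Reading never rescales
fundus intensities; bit depth is preserved as decoded.
"""

from __future__ import annotations

import glob
import os

import imageio.v3 as iio
import numpy as np

from .types import FundusImage, format_max

__all__ = [
    "read_fundus",
    "read_mask",
    "write_mask",
    "dataset_pairs",
]


def read_fundus(path: str | os.PathLike) -> FundusImage:
    """Read a color fundus photograph from PNG/TIFF/JPEG/PPM.

    An alpha channel, if present, is discarded.  Grayscale rasters are
    rejected: the pipeline needs the green channel of a color image.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read fundus image {path!r}: {exc}") from exc
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ValueError(f"{path!r} is not a color fundus image (single channel)")
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path!r}: unsupported raster shape {arr.shape}")
    return FundusImage(pixels=arr[:, :, :3], source_path=str(path))


def read_mask(path: str | os.PathLike, threshold_fraction: float = 0.5) -> np.ndarray:
    """Read a binary mask raster, binarizing at a fraction of the format max.

    Nominally binary gold-standard masks are occasionally antialiased; any
    pixel at or above ``threshold_fraction`` of the format's white level is
    foreground.  Multi-channel rasters are reduced by channel mean first.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    white = format_max(arr.dtype)
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return (arr >= threshold_fraction * white).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as an 8-bit raster with vessel=255."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    out = ((mask > 0).astype(np.uint8)) * np.uint8(255)
    try:
        iio.imwrite(path, out)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot write mask {path!r}: {exc}") from exc


# Dataset layouts: (images subdir+glob, gold subdir+glob, fov subdir+glob).
# Purely local globbing; no downloads are performed here.
_LAYOUTS: dict[str, tuple[str, str, str | None]] = {
    "drive": ("images/*.tif", "1st_manual/*.gif", "mask/*.gif"),
    "stare": ("stare-images/*.ppm", "labels-ah/*.ppm", None),
    "hrf": ("images/*.jpg", "manual1/*.tif", "mask/*.tif"),
}


def _stem(path: str) -> str:
    base = os.path.basename(path)
    return base.split(".")[0].split("_")[0]


def dataset_pairs(root: str | os.PathLike, layout: str) -> list[dict[str, str | None]]:
    """Pair images with gold-standard (and FOV) masks in a dataset directory.

    ``layout`` is one of ``drive``, ``stare``, ``hrf``.  Files are matched by
    leading filename stem; entries without a gold mask are skipped.
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(_LAYOUTS)}")
    img_glob, gold_glob, fov_glob = _LAYOUTS[layout]
    root = os.fspath(root)
    golds = {_stem(p): p for p in glob.glob(os.path.join(root, gold_glob))}
    fovs = (
        {_stem(p): p for p in glob.glob(os.path.join(root, fov_glob))} if fov_glob else {}
    )
    pairs = []
    for img in sorted(glob.glob(os.path.join(root, img_glob))):
        stem = _stem(img)
        if stem in golds:
            pairs.append({"image": img, "gold": golds[stem], "fov": fovs.get(stem)})
    return pairs
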