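"""End-to-end segmentation orchestration and the parameter-robustness study.

The "hierarchy" backend runs: preprocess -> invert (vessels become bright
ridges) -> Gaussian pyramid -> per-level vesselness at fixed sigma=1 ->
specular-reflex correction at the coarsest level -> per-level bilinear
upsampling -> per-level hysteresis binarization -> OR fusion -> gradient
thinning -> closing -> size cleanup.

The "frangi_reference" backend replaces the pyramid with the classical
linear sigma sweep (1..t in steps of 1) on the full-resolution image,
followed by a single hysteresis binarization, closing and cleanup.  Both
backends are deterministic: identical input and config give bit-identical
masks.

Because the pyramid shrinks each level by 4x in pixel count, the total
vesselness work is a geometric series bounded by 1.5x the full-resolution
pixel count, versus t passes over the full image for the sigma sweep;
``SegmentationDetails.vesselness_pixels`` exposes the actual count.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binarize import fraction_to_threshold, hysteresis_threshold, seed_noise_floor
from .config import SegmentationConfig
from .metrics import evaluate
from .postprocess import clean_objects, fuse_or, morph_close, thin_to_gradient
from .preprocess import preprocess
from .pyramid import build_hierarchy, choose_levels, upsample_to
from .reflex import correct_specular_reflex
from .types import FundusImage
from .vesselness import (
    eigenvalues_sym2x2,
    hessian_at_scale,
    multiscale_frangi_reference,
    vesselness,
)

__all__ = [
    "SegmentationDetails",
    "segment",
    "run_ablation",
    "default_ablation",
    "calibrate_fractions",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentationDetails:
    """Intermediates and instrumentation of one segmentation run."""

    mask: np.ndarray
    preprocessed: np.ndarray
    level_vesselness: list[np.ndarray] = field(default_factory=list)
    level_masks: list[np.ndarray] = field(default_factory=list)
    fused: np.ndarray | None = None
    vesselness_pixels: int = 0
    n_pixels: int = 0
    n_levels: int = 1


def _as_fundus(img: FundusImage | np.ndarray) -> FundusImage:
    if isinstance(img, FundusImage):
        return img
    return FundusImage(pixels=np.asarray(img))


def segment(
    img: FundusImage | np.ndarray,
    cfg: SegmentationConfig | None = None,
    details: bool = False,
) -> np.ndarray | SegmentationDetails:
    """Segment the vessel tree of a color fundus image.

    Returns the {0,1} uint8 vessel mask, or a :class:`SegmentationDetails`
    carrying intermediates when ``details`` is True.
    """
    cfg = cfg or SegmentationConfig()
    img = _as_fundus(img)
    t0 = time.perf_counter()
    pre = preprocess(img, cfg.preprocess)
    working = 1.0 - pre if cfg.frangi.polarity == "dark" else pre
    shape = working.shape

    if cfg.backend == "frangi_reference":
        det = _segment_reference(working, pre, shape, cfg)
    else:
        det = _segment_hierarchy(working, pre, shape, cfg)
    log.info(
        "segment: backend=%s levels=%d %.2fs, %d vessel px",
        cfg.backend,
        det.n_levels,
        time.perf_counter() - t0,
        int(det.mask.sum()),
    )
    return det if details else det.mask


def _postprocess(fused: np.ndarray, pre: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    pp = cfg.postprocess
    if not pp.enabled:
        return fused.astype(np.uint8)
    m = fused
    if pp.thinning:
        m = thin_to_gradient(m, pre)
    m = morph_close(m, pp.closing_size)
    min_obj, max_hole = pp.scaled_sizes(pre.shape[1])
    return clean_objects(m, min_obj, max_hole)


def _cap_levels_for_kernel(shape: tuple[int, int], n_levels: int, sigma: float) -> int:
    """Deepest hierarchy whose coarsest level still fits the derivative
    kernel support (2*ceil(4 sigma)+1 pixels per side)."""
    need = 2 * int(np.ceil(4 * sigma)) + 1
    k = n_levels
    while k > 1 and (
        -(-shape[0] // 2 ** (k - 1)) < need or -(-shape[1] // 2 ** (k - 1)) < need
    ):
        k -= 1
    return k


def _segment_hierarchy(
    working: np.ndarray, pre: np.ndarray, shape: tuple[int, int], cfg: SegmentationConfig
) -> SegmentationDetails:
    if cfg.pyramid.n_levels == "auto":
        n_levels = choose_levels(shape, cfg.pyramid.max_vessel_width)
    else:
        n_levels = int(cfg.pyramid.n_levels)
    capped = _cap_levels_for_kernel(shape, n_levels, cfg.frangi.sigma)
    if capped < n_levels:
        log.info(
            "hierarchy depth capped %d -> %d: sigma=%g kernel needs larger levels",
            n_levels, capped, cfg.frangi.sigma,
        )
        n_levels = capped
    levels = build_hierarchy(
        working, n_levels, sigma_aa=cfg.pyramid.sigma_aa,
        literal_order=cfg.pyramid.literal_order,
    )
    det = SegmentationDetails(
        mask=np.zeros(shape, np.uint8), preprocessed=pre,
        n_pixels=working.size, n_levels=n_levels,
    )
    for k, lev in enumerate(levels):
        h = hessian_at_scale(lev, cfg.frangi.sigma)
        v = vesselness(eigenvalues_sym2x2(h), cfg.frangi, level_index=k)
        det.vesselness_pixels += lev.size
        hp = cfg.binarize.at_level(k)
        # threshold statistics come from the uncorrected response and the
        # native-resolution map: the reflex correction repairs known
        # artifact sites and must not shift the protocol quantiles, and
        # interpolation during upsampling dilutes the noise median
        floor = seed_noise_floor(v.v0, hp.seed_floor_factor)
        raw_up = upsample_to(v.v0, shape)
        t_high = max(fraction_to_threshold(raw_up, hp.high_fraction), floor)
        t_low = fraction_to_threshold(raw_up, hp.low_fraction)
        if cfg.reflex.enabled and cfg.reflex.applies_at(k, n_levels):
            # reflex = bright stripe, so guide with the non-inverted image
            v.v0 = correct_specular_reflex(v.v0, 1.0 - lev)
            up = upsample_to(v.v0, shape)
        else:
            up = raw_up
        det.level_vesselness.append(up)
        mk = hysteresis_threshold(up, hp, t_high=t_high, t_low=t_low)
        log.debug("level %d: t_high=%.4g t_low=%.4g, %d px labeled",
                  k, t_high, t_low, int(mk.sum()))
        det.level_masks.append(mk)
    det.fused = fuse_or(det.level_masks)
    det.mask = _postprocess(det.fused, pre, cfg)
    return det


def _segment_reference(
    working: np.ndarray, pre: np.ndarray, shape: tuple[int, int], cfg: SegmentationConfig
) -> SegmentationDetails:
    # classical sweep: sigma from the base scale up to the thickest
    # expected vessel, in steps of 1
    t = max(cfg.frangi.sigma, float(cfg.pyramid.max_vessel_width))
    vm = multiscale_frangi_reference(working, cfg.frangi.sigma, t, 1.0, cfg.frangi)
    n_sigmas = int((t - cfg.frangi.sigma) // 1.0) + 1
    det = SegmentationDetails(
        mask=np.zeros(shape, np.uint8), preprocessed=pre,
        n_pixels=working.size, n_levels=1,
        vesselness_pixels=working.size * n_sigmas,
    )
    det.level_vesselness.append(vm.v0)
    mk = hysteresis_threshold(vm.v0, cfg.binarize.at_level(0))
    det.level_masks.append(mk)
    det.fused = mk
    pp = cfg.postprocess
    if pp.enabled:
        m = morph_close(mk, pp.closing_size)
        min_obj, max_hole = pp.scaled_sizes(pre.shape[1])
        m = clean_objects(m, min_obj, max_hole)
    else:
        m = mk
    det.mask = m.astype(np.uint8)
    return det


# -- parameter robustness -------------------------------------------------


def default_ablation() -> dict[str, dict]:
    """Standard robustness variants: skip a stage or nudge a parameter."""
    return {
        "baseline": {},
        "no_preprocess": {"preprocess.enabled": False},
        "thresholds_down_1pct": {"binarize.fraction_delta": -0.01},
        "thresholds_up_1pct": {"binarize.fraction_delta": +0.01},
        "no_postprocess": {"postprocess.enabled": False},
        "doubled_kernel": {"postprocess.closing_size": 6},
        "sigma_2": {"frangi.sigma": 2.0},
        "sigma_3": {"frangi.sigma": 3.0},
        "sigma_4": {"frangi.sigma": 4.0},
    }


def _apply_overrides(cfg: SegmentationConfig, overrides: dict) -> SegmentationConfig:
    out = copy.deepcopy(cfg)
    for key, val in overrides.items():
        if key == "binarize.fraction_delta":
            for attr, lo in (("high_fraction", 1e-4), ("low_fraction", 2e-4)):
                cur = getattr(out.binarize, attr)
                new = np.clip(np.asarray(cur, dtype=float) + val, lo, 0.9999)
                setattr(out.binarize, attr, float(new) if np.isscalar(cur) else new.tolist())
            continue
        obj = out
        parts = key.split(".")
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise ValueError(f"unknown config section {part!r} in {key!r}")
            obj = getattr(obj, part)
        if not hasattr(obj, parts[-1]):
            raise ValueError(f"unknown config field {key!r}")
        setattr(obj, parts[-1], val)
    return out


def run_ablation(
    dataset: list[tuple[FundusImage | np.ndarray, np.ndarray]],
    cfg: SegmentationConfig | None = None,
    variants: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Se/Sp/Acc per config variant, averaged over (image, gold) pairs.

    ``variants`` maps a variant name to dotted config overrides (e.g.
    ``{"frangi.sigma": 2.0}``); the special key
    ``binarize.fraction_delta`` shifts both hysteresis fractions.  The
    returned frame also carries each variant's accuracy change against
    the baseline (first variant with no overrides, added if missing).
    """
    cfg = cfg or SegmentationConfig()
    variants = variants if variants is not None else default_ablation()
    if not any(not v for v in variants.values()):
        variants = {"baseline": {}, **variants}
    rows = []
    for name, over in variants.items():
        vcfg = _apply_overrides(cfg, over)
        se, sp, acc = [], [], []
        for img, gold in dataset:
            r = evaluate(segment(img, vcfg), gold)
            se.append(r.sensitivity)
            sp.append(r.specificity)
            acc.append(r.accuracy)
        rows.append(
            {
                "variant": name,
                "sensitivity": float(np.nanmean(se)),
                "specificity": float(np.nanmean(sp)),
                "accuracy": float(np.mean(acc)),
            }
        )
    df = pd.DataFrame(rows).set_index("variant")
    base = df.loc[[n for n, o in variants.items() if not o][0], "accuracy"]
    df["delta_accuracy"] = df["accuracy"] - base
    return df


def calibrate_fractions(
    dataset: list[tuple[FundusImage | np.ndarray, np.ndarray]],
    cfg: SegmentationConfig | None = None,
    candidates: list[dict] | None = None,
    objective: str = "dice",
) -> tuple[SegmentationConfig, pd.DataFrame]:
    """Per-protocol threshold calibration on a small image subset.

    The hysteresis pixel fractions depend on the vessel/background ratio
    of an acquisition protocol and must be optimized per protocol on a
    few images with gold standards.  Each candidate is a dict of config
    overrides (as in :func:`run_ablation`); the one maximizing the mean
    ``objective`` ("dice" or "accuracy") over the dataset wins.  Returns
    the winning config and the score table.
    """
    from .metrics import dice as _dice

    cfg = cfg or SegmentationConfig()
    if candidates is None:
        candidates = [
            {"binarize.high_fraction": h, "binarize.low_fraction": l}
            for h in (0.01, 0.02, 0.03)
            for l in (0.08, 0.10, 0.12, 0.14)
        ]
    if objective not in ("dice", "accuracy"):
        raise ValueError("objective must be 'dice' or 'accuracy'")
    rows = []
    best = (-np.inf, cfg)
    for i, over in enumerate(candidates):
        vcfg = _apply_overrides(cfg, over)
        scores = []
        for img, gold in dataset:
            mask = segment(img, vcfg)
            if objective == "dice":
                scores.append(_dice(mask, gold))
            else:
                scores.append(evaluate(mask, gold).accuracy)
        score = float(np.mean(scores))
        rows.append({"candidate": i, **over, objective: score})
        if score > best[0]:
            best = (score, vcfg)
    return best[1], pd.DataFrame(rows)
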