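"""Full pipeline configuration, YAML-serializable.

Every stage parameter lives here so that a run is reproducible from a
single YAML document.  Defaults target low-resolution fundus photographs
(vessels up to ~16 px); high-resolution protocols raise
``pyramid.max_vessel_width`` (which deepens the hierarchy) and tune the
binarization fractions to their vessel/background ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .binarize import HysteresisParams
from .postprocess import PostprocessParams
from .preprocess import PreprocessParams
from .vesselness import FrangiParams

__all__ = ["PyramidParams", "ReflexParams", "SegmentationConfig"]


@dataclass
class PyramidParams:
    """Hierarchy depth settings; "auto" derives the depth from the
    thickest expected vessel width (in pixels at full resolution)."""

    n_levels: int | str = "auto"
    max_vessel_width: float = 16.0
    literal_order: bool = False
    sigma_aa: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.n_levels, str) and self.n_levels != "auto":
            raise ValueError("n_levels must be an integer or 'auto'")


@dataclass
class ReflexParams:
    """Where to apply specular-reflex correction in the hierarchy.

    ``levels`` is "coarsest", "all", or an integer n meaning the n
    coarsest levels; a reflex stripe depresses the ridge response at the
    pyramid levels matched to its vessel's width, which for wide width
    ranges spans more than the single coarsest level.
    """

    enabled: bool = True
    levels: str | int = "coarsest"

    def __post_init__(self) -> None:
        if isinstance(self.levels, str):
            if self.levels not in ("coarsest", "all"):
                raise ValueError(
                    "reflex levels must be 'coarsest', 'all' or a positive integer"
                )
        elif self.levels < 1:
            raise ValueError("reflex levels count must be >= 1")

    def applies_at(self, level: int, n_levels: int) -> bool:
        if self.levels == "all":
            return True
        if self.levels == "coarsest":
            return level == n_levels - 1
        return level >= n_levels - int(self.levels)


@dataclass
class SegmentationConfig:
    """Complete parameterization of a segmentation run.

    ``backend`` selects the multiresolution pipeline ("hierarchy") or the
    classical linear sigma-sweep ("frangi_reference") used for
    comparison.  The pipeline itself is deterministic; ``seed`` only
    feeds stochastic fixtures such as phantom generation.
    """

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    frangi: FrangiParams = field(default_factory=FrangiParams)
    pyramid: PyramidParams = field(default_factory=PyramidParams)
    reflex: ReflexParams = field(default_factory=ReflexParams)
    binarize: HysteresisParams = field(default_factory=HysteresisParams)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    backend: str = "hierarchy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("hierarchy", "frangi_reference"):
            raise ValueError("backend must be 'hierarchy' or 'frangi_reference'")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SegmentationConfig":
        kw: dict[str, Any] = {}
        sections = {
            "preprocess": PreprocessParams,
            "frangi": FrangiParams,
            "pyramid": PyramidParams,
            "reflex": ReflexParams,
            "binarize": HysteresisParams,
            "postprocess": PostprocessParams,
        }
        for key, val in d.items():
            if key in sections:
                kw[key] = sections[key](**val) if isinstance(val, dict) else val
            else:
                kw[key] = val
        return cls(**kw)

    @classmethod
    def from_yaml(cls, text: str) -> "SegmentationConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def load(cls, path: str) -> "SegmentationConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
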