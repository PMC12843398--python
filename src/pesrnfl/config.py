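"""Run configuration: every tunable of the pipeline in one serializable tree.

Defaults are tied to a base working scale of 32 px/deg (a 1440-px-wide,
45-deg field of view); window-like pixel sizes are rescaled with the actual
px_per_deg where noted in the consuming modules.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import yaml

log = logging.getLogger("pesrnfl")

#: Pixel-per-degree scale at which pixel-sized defaults are expressed.
BASE_PX_PER_DEG = 32.0


@dataclass
class PreprocessConfig:
    median_kernel: Optional[int] = None  # None: 3 at <=1500 px width, else 5
    sigmoid_gain: float = 10.0
    sigmoid_cutoff: float = 0.5
    roi_threshold: float = 0.05


@dataclass
class VesselConfig:
    sigmas: tuple = (1.0, 2.0, 3.0, 4.0)  # px at BASE_PX_PER_DEG, rescaled
    beta: float = 0.5
    c: Optional[float] = None  # None: half max Hessian Frobenius norm in ROI
    clahe_clip_limit: float = 0.01
    clahe_tiles: tuple = (8, 8)
    mask_method: str = "otsu"
    mask_threshold: Optional[float] = None
    min_component_px: int = 50  # at BASE_PX_PER_DEG, rescaled by scale**2


@dataclass
class ExtractionConfig:
    mm_window: int = 15  # px at BASE_PX_PER_DEG, rescaled (kept odd)
    min_segment_size: int = 20


@dataclass
class ReferenceConfig:
    dphi0_deg: float = 1.0
    r_max_deg: float = 45.0
    dr_deg: float = 1.0
    map_px_per_deg: float = 3.0
    window_margin_deg: float = 5.0
    raphe_full_circle: bool = False


@dataclass
class BundleConfig:
    order_n: int = 10
    link_radius_deg: float = 2.5
    tol_individual_deg: float = 25.0
    tol_group_deg: float = 35.0


@dataclass
class MappingConfig:
    resolution: tuple = (2300, 3500)  # rows, cols of the working raster
    extent_x_deg: float = 30.0  # raster spans x,y in [-extent, +extent]
    radius_deg: float = 0.86
    dilate_px: int = 1


@dataclass
class StatsConfig:
    p_threshold: float = 0.001
    min_eyes: int = 20
    use_aicc: bool = False


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    vessels: VesselConfig = field(default_factory=VesselConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    bundles: BundleConfig = field(default_factory=BundleConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    out_dir: str = "pes_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
                kwargs[f.name] = f.type(**v)
            elif f.name in _GROUPS:
                sub = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
                kwargs[f.name] = _GROUPS[f.name](**sub)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_GROUPS = {
    "preprocess": PreprocessConfig,
    "vessels": VesselConfig,
    "extraction": ExtractionConfig,
    "reference": ReferenceConfig,
    "bundles": BundleConfig,
    "mapping": MappingConfig,
    "stats": StatsConfig,
}
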