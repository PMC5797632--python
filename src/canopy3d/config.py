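"""Pipeline configuration.

All tunable parameters of the reconstruction / segmentation / trait pipeline
live in one serializable object so every run can echo the resolved
configuration next to its outputs.  Defaults follow the field protocol the
pipeline was designed around: a nadir time-of-flight RGB-D camera mounted
2.4 m above ground over 1.52 m rows, 0.05 m rasterization grid, excess-green
threshold 0.15, 30th-percentile height binarization and a 15-pixel
connected-component area threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class MLESACParams:
    """Robust ground-plane fit settings.

    iterations: number of 3-point hypotheses sampled.
    sigma: inlier noise scale in meters (truncated-quadratic cost scale).
    min_inlier_fraction: below this the fit is reported as not found and the
        ground normal is assumed to be the +z axis.
    max_tilt_deg: a fitted normal further than this from vertical is
        rejected (vegetation covering the ground, not a ground plane).
    """

    iterations: int = 500
    sigma: float = 0.02
    min_inlier_fraction: float = 0.2
    max_tilt_deg: float = 15.0
    seed: int = 0


@dataclass
class IntrinsicsConfig:
    """Pinhole depth-camera intrinsics (defaults: Kinect-v2-class sensor)."""

    fx: float = 365.0
    fy: float = 365.0
    cx: float = 256.0
    cy: float = 212.0
    width: int = 512
    height: int = 424


@dataclass
class PipelineConfig:
    intrinsics: IntrinsicsConfig = field(default_factory=IntrinsicsConfig)
    camera_height: float = 2.4          # m above ground
    enclosure_width: float = 1.52       # m, across-row ROI width (row spacing)
    mlesac: MLESACParams = field(default_factory=MLESACParams)
    exg_threshold: float = 0.15         # excess-green vegetation cut
    grid_size: float = 0.05             # m, rasterization cell edge
    binarize_percentile: float = 30.0   # height percentile for binarization
    cc_area_threshold: int = 15         # pixels, small-component removal
    alpha: float = 0.10                 # m, alpha-shape characteristic length
    width_segments: int = 10            # along-row bins for canopy width
    width_include_empty: bool = False   # include empty bins in mean width
    main_cc_axis: int = 1               # raster axis treated as the row axis
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "intrinsics" in d and isinstance(d["intrinsics"], dict):
            d["intrinsics"] = IntrinsicsConfig(**d["intrinsics"])
        if "mlesac" in d and isinstance(d["mlesac"], dict):
            d["mlesac"] = MLESACParams(**d["mlesac"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
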