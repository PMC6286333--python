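"""Run configuration: every tunable of the scan-to-index pipeline.

Defaults are the operating constants of the screening system: 650 mm body
size gate, 10th-order width polynomial, 90% width restriction, 50 degree
normal gate, +/-5 degree restarts at 1.25 degree intervals, 50 ICP
iterations, 25 mm estimation radii, 100 mm colormap gate, 3 mm grids,
alpha = 0.9, and posture limits of 7.5 degrees about x and 15 about y.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .registration import ICPConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    smoothing_radius: float = 5.0            # mm, moving-average window
    segmentation_angle_threshold: float = 10.0   # degrees, region growing
    segmentation_neighbors: int = 10
    normal_radius: float = 25.0              # mm, r5 for normals/curvature
    image_dx: float = 3.0                    # mm, boundary-image pixels
    image_dy: float = 3.0
    polynomial_order: int = 10
    icp: ICPConfig = field(default_factory=ICPConfig)
    colormap_gate: float = 100.0             # mm, stage-7 distance cutoff
    colormap_scale_max: float = 10.0         # mm, rendering saturation
    compute_colormap: bool = True
    colormap_max_points: int | None = 5000   # subsample rays for display
    grid_dx: float = 3.0                     # mm, resampling grid
    grid_dy: float = 3.0
    resample_radius: float = 25.0            # mm, r8
    alpha: float = 0.9                       # valid-range fraction
    posture_limit_x: float = 7.5             # degrees
    posture_limit_y: float = 15.0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "icp" in d and isinstance(d["icp"], dict):
            d["icp"] = ICPConfig(**d["icp"])
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
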