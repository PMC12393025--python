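"""Run configuration: one serializable object holding every analysis knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """All tunable parameters of a tracking/analysis run.

    Serializable to a single YAML file so any batch run can be reproduced from
    its logged configuration and seed.
    """

    # calibration / acquisition
    um_per_px: float = 5.0
    fps: int = 15
    # segmentation
    threshold: float = 120.0
    polarity: str = "worm-dark"
    min_area: int = 3000
    smooth_window: int = 5
    corner_span: int = 15
    threshold_step: float = 5.0
    max_retries: int = 10
    # analysis marker selections
    movement_marker: str = "centroid"  # or "1".."13"
    bending_marker: int = 6  # mid-body
    # bending
    max_bend_min_angle_deg: float = 20.0
    # curvature
    curvature_min_frac: float = 0.03
    primary_curvature_min: float = 2.5
    # sleep
    sleep_threshold_um: float = 10.0
    sleep_onset_k: int = 3
    sleep_wake_k: int = 3
    sleep_frame_interval_s: float = 10.0
    # action potentials
    ap_lead_ms: float | None = None  # required for the fixed-lead method
    ap_dvdt_criterion: float = 10.0
    ap_rmp_window_ms: float = 20.0
    ap_rmp_sub_ms: float = 3.0
    # randomness
    seed: int = 0

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **overrides) -> "AnalysisConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return AnalysisConfig(**data)


def calibrate(known_distance_um: float, pixel_distance: float) -> float:
    """Pixel-to-micrometer conversion factor from a known distance."""
    if known_distance_um <= 0 or pixel_distance <= 0:
        raise ValueError("calibration distances must be positive")
    return known_distance_um / pixel_distance
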