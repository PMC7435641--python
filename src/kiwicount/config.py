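"""Pipeline configuration: every tunable, validated, hashable.

Defaults encode the deployed operating point: a 24 px base window, 6
cascade stages with a 20% per-stage rejection rate and 99.5% per-stage
minimum detection rate, detection on the background-suppressed image, and a
97.95 g representative fruit weight.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # Detector geometry and training scale
    window: int = 24
    n_stages: int = 6
    rejection_rate: float = 20.0
    d_min: float = 99.5
    stage_rounds: list[int] = field(
        default_factory=lambda: [2, 4, 8, 16, 24, 32])
    train_positives: int = 250
    train_negatives: int = 1000
    bootstrap_negatives: int = 20000
    feature_position_stride: int = 3
    feature_size_stride: int = 3
    feature_min_size: int = 6
    full_feature_pool: bool = False
    variance_normalize: bool = False
    # Multi-scale scanning
    scale_factor: float = 1.25
    stride: int = 2
    max_scales: int = 3
    group_iou: float = 0.3
    detect_on_masked: bool = True
    # Background suppression
    median_window: int = 25
    dilation_radius: int = 12
    # Stitching
    max_keypoints: int = 500
    ratio_test: float = 0.75
    ransac_threshold: float = 3.0
    ransac_max_trials: int = 2000
    canvas_cap: int = 8000
    frame_stride: int = 1
    # Yield
    representative_weight: float = 97.95
    # Determinism
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 12:
            raise ValueError("window must be >= 12")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if not 0.0 < self.rejection_rate < 100.0:
            raise ValueError("rejection_rate must be in (0, 100)")
        if not 0.0 < self.d_min <= 100.0:
            raise ValueError("d_min must be in (0, 100]")
        if self.scale_factor <= 1.0:
            raise ValueError("scale_factor must be > 1")
        if self.stride < 1 or self.max_scales < 1 or self.frame_stride < 1:
            raise ValueError("stride, max_scales, frame_stride must be >= 1")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be an odd integer >= 3")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")
        if self.representative_weight <= 0:
            raise ValueError("representative_weight must be > 0")
        if not 0.0 < self.ratio_test <= 1.0:
            raise ValueError("ratio_test must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML key-value file; unknown keys are rejected."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
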