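"""Pipeline configuration: defaults, YAML loading, dictionary round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import DEFAULT_EARLY_THRESHOLD, DEFAULT_PEAK_THRESHOLD, PEAK_TIMEPOINTS
from .imaging import RoiParams


@dataclass
class PipelineConfig:
    """All tunables of the score -> classify -> stats pipeline.

    Cohort parameters: ``k`` clusters (default 7), ``restarts`` k-means
    starts, clustering ``feature_timepoints`` (default 2, 4, 7 dph;
    0, 2, 4, 7 is the documented alternative), and the status thresholds
    (early >= 0.29 on the centroid average; delayed < 0.33 on the centroid
    post-baseline peak).
    """

    roi: RoiParams = field(default_factory=RoiParams)
    k: int = 7
    restarts: int = 100
    seed: int = 0
    feature_timepoints: tuple[int, ...] = PEAK_TIMEPOINTS
    standardize: bool = False
    early_threshold: float = DEFAULT_EARLY_THRESHOLD
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD
    alpha: float = 0.05
    posthoc_method: str = "lsd"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "roi" in data and isinstance(data["roi"], dict):
            data["roi"] = RoiParams(**data["roi"])
        if "feature_timepoints" in data:
            data["feature_timepoints"] = tuple(data["feature_timepoints"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
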