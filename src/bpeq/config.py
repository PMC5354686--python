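"""Study configuration: every tunable the pipeline exposes, with validation.

The file format is YAML with the same nesting as the dataclasses below.
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .volume import PHASE_MINUTES


def _from_mapping(cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"{cls.__name__} section must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SegmentationConfig:
    smoothness: int = 2  # max |row step| per column in the DP path
    band_width: int = 3  # cross-slice continuity band, voxels
    sigma: float = 1.0  # gradient smoothing scale, voxels
    crop_fraction: float = 1.0  # in-plane VOI crop around the body centroid
    k_range: tuple[int, int] = (2, 5)
    validity_index: str = "xie-beni"
    m: float = 2.0  # FCM fuzziness exponent
    top_clusters: int = 1  # clusters labelled FGT, counted from the brightest
    z: float = 3.0  # enhancement threshold in noise units
    noise_margin: int = 3  # skin standoff of the air reference region

    def __post_init__(self) -> None:
        if self.smoothness < 1 or self.band_width < 0:
            raise ValueError("smoothness >= 1 and band_width >= 0 required")
        if self.sigma <= 0 or not 0.2 < self.crop_fraction <= 1.0:
            raise ValueError("sigma > 0 and crop_fraction in (0.2, 1] required")
        self.k_range = tuple(self.k_range)  # type: ignore[assignment]
        if not (2 <= self.k_range[0] <= self.k_range[1] <= 8):
            raise ValueError(f"k_range must lie within [2, 8], got {self.k_range}")
        if self.validity_index not in ("xie-beni", "partition-coefficient"):
            raise ValueError(f"unknown validity index {self.validity_index!r}")
        if self.m <= 1 or self.z <= 0 or self.top_clusters < 1:
            raise ValueError("m > 1, z > 0 and top_clusters >= 1 required")


@dataclass
class StatsConfig:
    auc_ci_method: str = "delong"  # or "hanley-mcneil"
    exact_mw_limit: int = 20  # exact Mann-Whitney up to this per-sample n

    def __post_init__(self) -> None:
        if self.auc_ci_method not in ("delong", "hanley-mcneil"):
            raise ValueError(f"unknown AUC CI method {self.auc_ci_method!r}")


@dataclass
class StudyConfig:
    phase_minutes: dict[str, float] = field(default_factory=lambda: dict(PHASE_MINUTES))
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.phase_minutes) != set(PHASE_MINUTES):
            raise ValueError(f"phase_minutes needs exactly the keys {sorted(PHASE_MINUTES)}")
        if isinstance(self.segmentation, dict):
            self.segmentation = _from_mapping(SegmentationConfig, self.segmentation)
        if isinstance(self.stats, dict):
            self.stats = _from_mapping(StatsConfig, self.stats)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return _from_mapping(cls, data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
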