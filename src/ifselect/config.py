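"""Pipeline configuration: one YAML-serializable object driving every stage.

All randomness flows from ``seed`` through :func:`ifselect._seeding.derive_seed`,
so two runs with equal configuration are identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ifs import CLASSIFIER_NAMES
from .ranking import available_rankers, canonical_ranker_name

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    top_n: int = 200
    step: int = 5
    cv_folds: int = 10
    rankers: list[str] = field(default_factory=available_rankers)
    classifiers: list[str] = field(default_factory=lambda: ["DT", "RF"])
    smote_k: int = 5
    relative_delta: float = 0.015
    relative_k_threshold: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.rankers = [canonical_ranker_name(r) for r in self.rankers]
        self.validate()

    def validate(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be positive")
        if not (1 <= self.step <= self.top_n):
            raise ValueError("step must satisfy 1 <= step <= top_n")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if not (0 <= self.relative_delta < 1):
            raise ValueError("relative_delta must be in [0, 1)")
        if self.relative_k_threshold < 1:
            raise ValueError("relative_k_threshold must be >= 1")
        bad = [c for c in self.classifiers if c not in CLASSIFIER_NAMES]
        if bad:
            raise ValueError(f"unknown classifiers {bad}; valid: {CLASSIFIER_NAMES}")
        if not self.rankers:
            raise ValueError("at least one ranker required")

    def to_yaml(self, path) -> None:
        payload = {"schema_version": CONFIG_SCHEMA_VERSION, **asdict(self)}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        version = payload.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema_version {version}; "
                f"expected {CONFIG_SCHEMA_VERSION}"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)
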