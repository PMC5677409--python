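"""Pipeline configuration: one object carrying every tunable parameter.

Defaults are the method's operating point: 10 Hz sampling, 30 s windows with
50% overlap (300 samples per window, stride 150), ApEn with m = 2 and
r = 0.2 sd, tree pruning confidence 0.25 with minimum leaf size 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import TreeParams
from .datamodel import ValidationError
from .features import ApEnParams, WindowConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    fs: float = 10.0
    tw: float = 30.0
    overlap: float = 0.5
    apen_m: int = 2
    apen_r_coef: float = 0.2
    pruning_confidence: float = 0.25
    min_leaf: int = 2
    feature_set: str = "std"
    target: str = "activity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in ("std", "apen", "both"):
            raise ValidationError(f"unknown feature set {self.feature_set!r}")
        if self.target not in ("activity", "level"):
            raise ValidationError(f"unknown target {self.target!r}")
        # constructing the component configs validates the numeric fields
        self.window()
        self.apen_params()
        self.tree_params()

    def window(self) -> WindowConfig:
        return WindowConfig(tw=self.tw, overlap=self.overlap, fs=self.fs)

    def apen_params(self) -> ApEnParams:
        return ApEnParams(m=self.apen_m, r_coef=self.apen_r_coef)

    def tree_params(self) -> TreeParams:
        return TreeParams(
            pruning_confidence=self.pruning_confidence, min_leaf=self.min_leaf
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
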