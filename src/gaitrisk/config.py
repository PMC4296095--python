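"""Pipeline configuration with YAML round-trip.

Defaults match the study constants this pipeline encodes: sample-entropy
template length 5 and tolerance 0.3, running filter at stride time 0.8 s and
VT RMS 5 m/s^2, stepwise alpha .05 with Spearman screen .7, and 1000
permutations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .comparison import PermutationSpec
from .features import FeatureConfig, LdsParams, SampEnParams, SpectralParams
from .summary import RunningFilterParams
from .synth import CohortParams


@dataclass
class StepwiseParams:
    alpha: float = 0.05
    rho_max: float = 0.7


@dataclass
class SummaryParams:
    percentiles: tuple = (10, 50, 90)
    min_support: int = 10


@dataclass
class PipelineConfig:
    """Everything needed to run simulate -> extract -> summarize -> fit -> compare."""

    cohort: CohortParams = field(default_factory=CohortParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    running_filter: RunningFilterParams = field(default_factory=RunningFilterParams)
    summary: SummaryParams = field(default_factory=SummaryParams)
    stepwise: StepwiseParams = field(default_factory=StepwiseParams)
    permutation: PermutationSpec = field(default_factory=PermutationSpec)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_dict(cls, d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """YAML-safe plain structures (tuples -> lists)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _from_dict(cls, d):
    if not is_dataclass(cls):
        return d
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        target = f.type if isinstance(f.type, type) else None
        # resolve nested dataclasses by default-factory inspection
        if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            proto = f.default_factory()  # type: ignore[misc]
            if is_dataclass(proto) and isinstance(v, dict):
                kwargs[f.name] = _from_dict(type(proto), v)
                continue
            if isinstance(proto, tuple) and isinstance(v, list):
                kwargs[f.name] = tuple(v)
                continue
        kwargs[f.name] = v
    return cls(**kwargs)
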