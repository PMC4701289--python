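"""Pipeline configuration: one YAML/JSON document drives every stage.

The schema mirrors the library dataclasses; unknown keys are rejected so a
typo never silently falls back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any, Mapping

import yaml

from .c45 import InductionParams
from .features import FeatureParams
from .segmentation import SegmentationParams
from .synthetic import CLASSES, ClassProfile, SensorModel, SessionSpec, default_profiles

__all__ = ["CVParams", "SessionParams", "PipelineConfig"]


def _from_mapping(cls, data: Mapping[str, Any], where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")
    return cls(**data)


@dataclass(frozen=True)
class CVParams:
    k: int = 10
    seed: int = 1
    stratified: bool = True


@dataclass(frozen=True)
class SessionParams:
    """Session recipe in config form (expanded to a SessionSpec)."""

    movements_per_class: int = 200
    order: tuple[str, ...] = CLASSES
    sampling_rate_hz: float = 1000.0
    inter_movement_gap_s: float = 0.1
    align_block_s: float | None = 1.0
    terminal_baseline_s: float = 1.0
    seed: int = 1

    def to_spec(self) -> SessionSpec:
        return SessionSpec(
            segments=tuple((c, self.movements_per_class) for c in self.order),
            sampling_rate_hz=self.sampling_rate_hz,
            inter_movement_gap_s=self.inter_movement_gap_s,
            align_block_s=self.align_block_s,
            terminal_baseline_s=self.terminal_baseline_s,
            seed=self.seed,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full simulate-to-report run."""

    sensor: SensorModel = field(default_factory=SensorModel)
    profiles: Mapping[str, ClassProfile] = field(default_factory=default_profiles)
    session: SessionParams = field(default_factory=SessionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    induction: InductionParams = field(default_factory=InductionParams)
    cv: CVParams = field(default_factory=CVParams)
    per_class_cap: int = 200

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in pipeline config")
        kwargs: dict[str, Any] = {}
        if "sensor" in data:
            kwargs["sensor"] = _from_mapping(SensorModel, data["sensor"], "sensor")
        if "profiles" in data:
            profiles = {}
            for label, body in data["profiles"].items():
                body = dict(body)
                body.setdefault("label", label)
                if body["label"] != label:
                    raise ValueError(f"profile key {label!r} disagrees with its label")
                profiles[label] = _from_mapping(
                    ClassProfile, body, f"profiles.{label}"
                )
            kwargs["profiles"] = profiles
        if "session" in data:
            body = dict(data["session"])
            if "order" in body:
                body["order"] = tuple(body["order"])
            kwargs["session"] = _from_mapping(SessionParams, body, "session")
        for key, sub in (
            ("segmentation", SegmentationParams),
            ("features", FeatureParams),
            ("induction", InductionParams),
            ("cv", CVParams),
        ):
            if key in data:
                kwargs[key] = _from_mapping(sub, data[key], key)
        if "per_class_cap" in data:
            kwargs["per_class_cap"] = int(data["per_class_cap"])
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        doc = {
            "sensor": asdict(self.sensor),
            "profiles": {k: asdict(v) for k, v in self.profiles.items()},
            "session": asdict(self.session),
            "segmentation": asdict(self.segmentation),
            "features": asdict(self.features),
            "induction": asdict(self.induction),
            "cv": asdict(self.cv),
            "per_class_cap": self.per_class_cap,
        }
        doc["session"]["order"] = list(self.session.order)
        return doc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
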