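"""Declarative pipeline configuration and run manifest.

One YAML file fixes every tunable of a run — acquisition geometry, task
design, preprocessing parameters, combination mode, RETROICOR order,
statistical thresholds, and all seeds; no stage draws randomness that is
not recorded here.  Unknown keys are rejected so silent typos cannot
change an analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import AcquisitionSpec, TaskDesign

__all__ = ["PreprocParams", "StatParams", "PipelineConfig", "SubjectRecord", "RunManifest"]


def _from_mapping(cls, mapping: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("te_list", "grid_shape", "voxel_size"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


@dataclass(frozen=True)
class PreprocParams:
    fwhm_mm: float = 6.0
    highpass_s: float = 50.0
    fd_threshold_mm: float = 0.4
    head_radius_mm: float = 50.0

    def __post_init__(self):
        if self.fwhm_mm < 0 or self.highpass_s <= 0 or self.fd_threshold_mm <= 0:
            raise ValueError("preprocessing parameters out of bounds")


@dataclass(frozen=True)
class StatParams:
    voxel_z: float = 2.32
    cluster_p: float = 0.05
    n_permutations: int = 1000

    def __post_init__(self):
        if not 0 < self.cluster_p < 1 or self.n_permutations < 100:
            raise ValueError("statistical thresholds out of bounds")


@dataclass(frozen=True)
class PipelineConfig:
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    task: TaskDesign = field(default_factory=TaskDesign)
    preprocessing: PreprocParams = field(default_factory=PreprocParams)
    combine_normalize: bool = True
    single_echo_te: float = 35.35
    retroicor_order: int = 2
    statistics: StatParams = field(default_factory=StatParams)
    seed: int = 0

    def __post_init__(self):
        if self.retroicor_order < 1:
            raise ValueError("retroicor_order must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(mapping) - allowed
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "acquisition" in kwargs:
            kwargs["acquisition"] = _from_mapping(AcquisitionSpec, kwargs["acquisition"])
        if "task" in kwargs:
            kwargs["task"] = _from_mapping(TaskDesign, kwargs["task"])
        if "preprocessing" in kwargs:
            kwargs["preprocessing"] = _from_mapping(PreprocParams, kwargs["preprocessing"])
        if "statistics" in kwargs:
            kwargs["statistics"] = _from_mapping(StatParams, kwargs["statistics"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        mapping = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(mapping)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration, used for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SubjectRecord:
    subject: str
    group: str
    echo_paths: list[str]
    events_path: str
    cardiac_path: str | None = None
    respiratory_path: str | None = None
    motion_path: str | None = None


@dataclass
class RunManifest:
    subjects: list[SubjectRecord] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        mapping = yaml.safe_load(Path(path).read_text()) or {}
        records = [
            _from_mapping(SubjectRecord, entry)
            for entry in mapping.get("subjects", [])
        ]
        return cls(subjects=records)

    def validate(self, base: str | Path = ".") -> None:
        """Check that every referenced file exists."""
        base = Path(base)
        missing = []
        for rec in self.subjects:
            paths = list(rec.echo_paths) + [rec.events_path]
            for p in (rec.cardiac_path, rec.respiratory_path, rec.motion_path):
                if p:
                    paths.append(p)
            for p in paths:
                q = Path(p)
                if not q.is_absolute():
                    q = base / q
                target = q if q.exists() else (
                    q / "trials.tsv" if q.suffix == "" else q
                )
                if not target.exists():
                    missing.append(str(q))
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")
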