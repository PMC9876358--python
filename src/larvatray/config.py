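"""Run configuration (YAML/JSON), validation and reproducibility manifests.

A run config bundles the container description, imaging parameters and
analysis options.  Unknown keys are rejected so a typo can never silently
fall back to a default, and every run can emit a manifest serialising all
effective settings (defaults included), the seed and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import Container


class ConfigError(ValueError):
    """Invalid run configuration."""


def _from_dict(cls, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class ImagingParams:
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    despeckle_passes: int = 1
    max_particle_area_px: int = 12

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "manual"):
            raise ConfigError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "manual" and self.manual_threshold is None:
            raise ConfigError("manual thresholding requires manual_threshold")
        if self.despeckle_passes < 0 or self.max_particle_area_px < 0:
            raise ConfigError("imaging parameters must be non-negative")


@dataclass(frozen=True)
class AnalysisParams:
    pi_formula: str = "ln100fs"
    dunn_adjust: str = "none"
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pi_formula not in ("ln100fs", "lnfs"):
            raise ConfigError(f"unknown PI formula {self.pi_formula!r}")
        if self.dunn_adjust not in ("none", "holm"):
            raise ConfigError(f"unknown Dunn adjustment {self.dunn_adjust!r}")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    container: Container
    px_per_cm: float = 25.0
    imaging: ImagingParams = field(default_factory=ImagingParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ConfigError("px_per_cm must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"container", "px_per_cm", "imaging", "analysis"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "container" not in d:
            raise ConfigError("config requires a 'container' section")
        try:
            container = Container.from_dict(dict(d["container"]))
        except ValueError as exc:
            raise ConfigError(f"invalid container: {exc}") from exc
        return cls(
            container=container,
            px_per_cm=d.get("px_per_cm", 25.0),
            imaging=_from_dict(ImagingParams, dict(d.get("imaging", {}))),
            analysis=_from_dict(AnalysisParams, dict(d.get("analysis", {}))),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)  # YAML is a JSON superset
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["container"] = {k: v for k, v in d["container"].items() if v is not None}
        return d

    def config_hash(self) -> str:
        """Hash of the fully-defaulted serialised config."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config: RunConfig | None, seed: int | None, outputs: dict) -> dict:
    """Write a reproducibility manifest next to a run's outputs.

    ``outputs`` maps logical names to file paths; their checksums, the
    effective config (all defaults serialised) and the seed are recorded so
    a run can be reproduced bit-exactly.
    """
    from . import __version__

    manifest = {
        "larvatray_version": __version__,
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
        "config_hash": config.config_hash() if config is not None else None,
        "outputs": {name: {"path": str(p), "sha256": file_checksum(p)}
                    for name, p in outputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
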