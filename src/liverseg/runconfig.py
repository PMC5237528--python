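"""Run configuration: one YAML file validated against every module's
config type before any computation starts.  Unknown keys are rejected so
typos fail loudly rather than silently falling back to defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cascade import ContextConfig
from .glcm import GLCMConfig
from .phantom import PhantomSpec
from .random_walk import RandomWalkConfig


@dataclass(frozen=True)
class BoostConfig:
    """Cascade training hyperparameters."""

    n_iterations: int = 4  # U: context-augmented stages
    n_rounds: int = 100  # boosting rounds per stage
    n_per_class: int = 2000  # training pixels sampled per class per slice

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.n_rounds < 1 or self.n_per_class < 1:
            raise ValueError("n_rounds and n_per_class must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    context: ContextConfig = field(default_factory=ContextConfig)
    boosting: BoostConfig = field(default_factory=BoostConfig)
    random_walk: RandomWalkConfig = field(default_factory=RandomWalkConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0
    log_level: str = "INFO"

    def digest(self) -> str:
        """Stable short hash of the full configuration, for run logs."""
        doc = json.dumps(_as_dict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


_SECTIONS = {
    "glcm": GLCMConfig,
    "context": ContextConfig,
    "boosting": BoostConfig,
    "random_walk": RandomWalkConfig,
    "phantom": PhantomSpec,
}

_TUPLE_FIELDS = {"offsets", "intensity_range", "radii", "image_size", "spacing"}


def _as_dict(cfg) -> dict:
    def conv(v):
        if dataclasses.is_dataclass(v):
            return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        return v

    return conv(cfg)


def _build_section(cls, doc: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    kwargs = {}
    for k, v in doc.items():
        if k in _TUPLE_FIELDS and v is not None:
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping of sections")
    known = set(_SECTIONS) | {"seed", "log_level"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in doc:
            if not isinstance(doc[name], dict):
                raise ValueError(f"config section [{name}] must be a mapping")
            kwargs[name] = _build_section(cls, doc[name], name)
    if "seed" in doc:
        kwargs["seed"] = int(doc["seed"])
    if "log_level" in doc:
        kwargs["log_level"] = str(doc["log_level"])
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=False)
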