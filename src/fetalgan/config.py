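"""YAML run configuration: schema-checked sections for every pipeline stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .models import BaselineUNetSpec, CriticSpec, GeneratorSpec
from .patching import PatchSpec
from .phantom import PhantomConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_SECTION_TYPES = {
    "phantom": PhantomConfig,
    "generator": GeneratorSpec,
    "critic": CriticSpec,
    "unet": BaselineUNetSpec,
    "train": TrainConfig,
}


@dataclass
class RunConfig:
    """Full pipeline configuration with one section per stage.

    Unknown keys are rejected with the offending field path so that typos in
    hand-written YAML fail loudly instead of silently using a default.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    critic: CriticSpec = field(default_factory=CriticSpec)
    unet: BaselineUNetSpec = field(default_factory=BaselineUNetSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    data_dir: str = "data"
    out_dir: str = "out"
    seed: int = 0
    n_phantoms: int = 10
    duplicate_subject_rate: float = 0.0

    def apply_seed(self, seed: int) -> "RunConfig":
        """Propagate a global seed into every seeded section."""
        cfg = dataclasses.replace(self, seed=seed)
        cfg.phantom = dataclasses.replace(self.phantom, seed=seed)
        cfg.generator = dataclasses.replace(self.generator, seed=seed + 1)
        cfg.critic = dataclasses.replace(self.critic, seed=seed + 2)
        cfg.unet = dataclasses.replace(self.unet, seed=seed + 3)
        cfg.train = dataclasses.replace(self.train, seed=seed)
        return cfg

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out


def _build_section(name: str, cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in section '{name}': "
                         + ", ".join(f"{name}.{k}" for k in sorted(unknown)))
    coerced = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError("unknown config key(s): " + ", ".join(sorted(unknown)))
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            section = raw[name]
            if not isinstance(section, dict):
                raise ValueError(f"config section '{name}' must be a mapping")
            kwargs[name] = _build_section(name, cls, section)
    for name in ("data_dir", "out_dir", "seed", "n_phantoms", "duplicate_subject_rate"):
        if name in raw:
            kwargs[name] = raw[name]
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration, for run logs."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
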