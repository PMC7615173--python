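"""Strict YAML run configuration.

A run config is a YAML mapping with optional sections ``network``,
``train``, ``loss``, ``phantom`` and ``split``, each mirroring the fields
of the corresponding dataclass.  Unknown sections or keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .network import NetworkSpec
from .objectives import LossConfig
from .phantom import PhantomSpec, SplitSpec
from .trainer import TrainConfig

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "network": NetworkSpec,
    "train": TrainConfig,
    "loss": LossConfig,
    "phantom": PhantomSpec,
    "split": SplitSpec,
}

_TUPLE_FIELDS = {"shape", "radius_range"}


class RunConfig:
    """Validated bundle of all run settings."""

    def __init__(self, network=None, train=None, loss=None, phantom=None, split=None):
        self.network = network or NetworkSpec()
        self.train = train or TrainConfig()
        self.loss = loss or LossConfig()
        self.phantom = phantom or PhantomSpec()
        self.split = split or SplitSpec()

    def __repr__(self):
        return (f"RunConfig(network={self.network}, train={self.train}, "
                f"loss={self.loss}, phantom={self.phantom}, split={self.split})")


def _build_section(cls, mapping: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    coerced = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
               for k, v in mapping.items()}
    return cls(**coerced)


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; ``overrides`` maps
    ``section.key`` to replacement values (CLI flags win over the file)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if section not in _SECTIONS:
            raise ValueError(f"unknown override section {section!r}")
        raw.setdefault(section, {})[key] = value
    built = {name: _build_section(cls, raw.get(name, {}) or {}, name)
             for name, cls in _SECTIONS.items()}
    return RunConfig(**built)
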