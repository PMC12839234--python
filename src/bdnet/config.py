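"""YAML run configuration: nested sections mapping onto the dataclasses.

Unknown keys are rejected (a typo'd hyperparameter silently falling back
to its default is the worst failure mode a training config can have).
Dotted command-line overrides like ``train.batch_size=8`` are supported.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .bdnet_arch import NetworkSpec
from .giel_losses import LossWeights
from .noise_model import NoiseParams
from .training import TrainConfig


class ConfigError(ValueError):
    pass


def _build(cls, section: dict[str, Any], name: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(section) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{name}': {', '.join(sorted(unknown))}")
    coerced = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


@dataclass
class RunConfig:
    """Composite configuration for a simulate/train/evaluate run."""

    network: NetworkSpec = field(default_factory=NetworkSpec)
    noise: NoiseParams = field(default_factory=NoiseParams)
    loss: LossWeights = field(default_factory=LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    log_level: str = "INFO"

    _SECTIONS = {"network": NetworkSpec, "noise": NoiseParams, "loss": LossWeights,
                 "train": TrainConfig}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        unknown = set(data) - set(cls._SECTIONS) - {"log_level"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
        kwargs: dict[str, Any] = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _build(section_cls, data[name] or {}, name)
        if "log_level" in data:
            kwargs["log_level"] = str(data["log_level"])
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path | None = None, overrides: list[str] | None = None) -> "RunConfig":
        data: dict[str, Any] = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        for item in overrides or []:
            if "=" not in item:
                raise ConfigError(f"override '{item}' must look like section.key=value")
            dotted, raw = item.split("=", 1)
            parts = dotted.split(".")
            if len(parts) != 2:
                raise ConfigError(f"override '{item}' must look like section.key=value")
            node = data.setdefault(parts[0], {})
            node[parts[1]] = yaml.safe_load(raw)
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [encode(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return {
            "network": encode(self.network),
            "noise": encode(self.noise),
            "loss": encode(self.loss),
            "train": encode(self.train),
            "log_level": self.log_level,
        }
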