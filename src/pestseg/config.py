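"""YAML run configuration: nested model / training / synthesis settings.

A run config round-trips through YAML unchanged; absent keys take
defaults, unknown keys are rejected so typos fail loudly, and invalid
values raise a validation error naming the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .blocks import InceptionConfig
from .model import ModelConfig
from .synthetic import SynthConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    out_dir: str = "runs"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"invalid log_level {self.log_level!r}")


_TUPLE_FIELDS = {
    "input_size",
    "size",
    "blobs_per_image",
    "blob_scale",
    "branch_rates",
    "branch_kernels",
}
_NESTED_TUPLE_FIELDS = {"foreground_color", "background_palette"}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or 'top level'} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        loc = f"{path}.{key}" if path else key
        if key in ("model", "train", "synth"):
            sub_cls = {"model": ModelConfig, "train": TrainConfig, "synth": SynthConfig}[key]
            kwargs[key] = _build(sub_cls, value or {}, loc)
        elif key == "inception":
            kwargs[key] = None if value is None else _build(InceptionConfig, value, loc)
        elif key in _TUPLE_FIELDS and value is not None:
            kwargs[key] = tuple(value)
        elif key in _NESTED_TUPLE_FIELDS and value is not None:
            kwargs[key] = tuple(tuple(v) for v in value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid config at {path or 'top level'}: {e}") from e


def load_config(path) -> RunConfig:
    """Parse a YAML file into a validated RunConfig; empty file = defaults."""
    p = Path(path)
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return _build(RunConfig, data, "")


def save_config(config: RunConfig, path) -> None:
    """Serialise a RunConfig to YAML (inverse of :func:`load_config`)."""
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, list):
            return [clean(v) for v in obj]
        return obj

    with open(Path(path), "w") as fh:
        yaml.safe_dump(clean(config), fh, sort_keys=False)
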