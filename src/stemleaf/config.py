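"""Run configuration: strict YAML schema with training defaults
(Adam, lr 1e-3, 100 epochs, 9:1 split)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .segnet import NetworkConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: str = "dice_boundary"
    boundary_weight: float = 1.0
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 100
    split_ratio: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split ratio must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.loss not in ("dice", "boundary", "dice_boundary"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.boundary_weight < 0:
            raise ValueError("boundary weight must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.as_dict()
        return d


def _strict(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path or a dict; unknown keys error."""
    if source is None:
        return RunConfig()
    if not isinstance(source, dict):
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = dict(source)
    _strict(RunConfig, data, "run")
    net = data.pop("network", {}) or {}
    _strict(NetworkConfig, net, "network")
    for key in ("decoder_widths", "aspp_rates"):
        if key in net:
            net[key] = tuple(net[key])
    return RunConfig(network=NetworkConfig(**net), **data)
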