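"""Round-trippable configuration files (JSON or YAML)."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
import json

import yaml

from .dynamics import NeuronParams, SynapseKinetics
from .network import NetworkConfig
from .stimulus import StimulusConfig

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]


def config_to_dict(cfg: NetworkConfig) -> dict:
    return asdict(cfg)


def config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    d["stimulus"] = StimulusConfig(**d.get("stimulus", {}))
    d["neuron"] = NeuronParams(**d.get("neuron", {}))
    d["kinetics"] = SynapseKinetics(**d.get("kinetics", {}))
    return NetworkConfig(**d)


def save_config(cfg: NetworkConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path, overrides: dict | None = None) -> NetworkConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if overrides:
        d.update(overrides)
    return config_from_dict(d)
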