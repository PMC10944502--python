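"""Run configuration: a YAML-round-trippable bundle of every knob and seed.

All the protocol constants (90-min shift = 18 samples, 50 epochs, batch 1,
5 critic updates per generator update, -1/+1 labels, glycaemic band edges)
are surfaced here as named keys so a run is fully described by one file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .controller import ControllerConfig
from .gan import TrainConfig
from .generation import LatentConfig

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    cohort_seed: int = 0
    n_patients: int = 2
    days: int = 7
    weeks_generated: float = 1.0
    train: TrainConfig = field(default_factory=TrainConfig)
    latent: LatentConfig = field(default_factory=LatentConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    granger_max_lag: int = 18
    ccm: dict = field(default_factory=lambda: {"E": 3, "tau": 1, "n_boot": 10})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {raw.get('schema_version')!r}"
            )
        raw["train"] = TrainConfig(**raw.get("train", {}))
        raw["latent"] = LatentConfig(**raw.get("latent", {}))
        raw["controller"] = ControllerConfig(**raw.get("controller", {}))
        return cls(**raw)
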