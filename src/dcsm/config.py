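"""YAML/JSON round-trip for model configurations.

A configuration file may carry any of three top-level sections:
``spec`` (structural switches), ``params`` (parameter values, e.g.
generating values for simulation or fixed starts for fitting) and
``design`` (the simulated observation process).  Parameter names in the
serialized form follow the in-memory structure of DCSMParams.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .dcsm_core import DCSMParams, DCSMSpec
from .synthetic_data import StudyDesign

__all__ = ["ModelConfig", "load_config", "save_config"]


@dataclass
class ModelConfig:
    spec: DCSMSpec | None = None
    params: DCSMParams | None = None
    design: StudyDesign | None = None

    def to_dict(self) -> dict:
        out = {}
        if self.spec is not None:
            out["spec"] = self.spec.to_dict()
        if self.params is not None:
            out["params"] = self.params.to_dict()
        if self.design is not None:
            out["design"] = self.design.to_dict()
        return out


def load_config(path: str | Path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ModelConfig(
        spec=DCSMSpec.from_dict(raw["spec"]) if "spec" in raw else None,
        params=DCSMParams.from_dict(raw["params"]) if "params" in raw else None,
        design=StudyDesign.from_dict(raw["design"]) if "design" in raw else None,
    )


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
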