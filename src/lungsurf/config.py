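"""Run configuration: thresholds, protocol and simulator defaults, seeds.

Every CLI output embeds the configuration hash and seed so a run can be
reproduced byte for byte from its artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, PositiveFloat, PositiveInt

from lungsurf.simulate import CyclingProtocol, FilmModelParams
from lungsurf.traces import AssayCriteria


class CriteriaConfig(BaseModel):
    baseline_max_st: PositiveFloat = 5.0
    inhibition_st: PositiveFloat = 10.0
    max_compression: PositiveFloat = 0.30
    run_length: PositiveInt = 3
    n_baseline_cycles: PositiveInt = 5
    replicate_rule: float = Field(0.5, gt=0, le=1)

    def build(self) -> AssayCriteria:
        return AssayCriteria(**self.model_dump())


class ProtocolConfig(BaseModel):
    cycle_rate: PositiveFloat = 20.0
    frame_rate: PositiveFloat = 10.0
    baseline_area: PositiveFloat = 50.0
    relative_amplitude: float = Field(0.25, gt=0, lt=1)
    duration: PositiveFloat = 120.0
    temperature: float = 37.0

    def build(self) -> CyclingProtocol:
        return CyclingProtocol(**self.model_dump())


class FilmConfig(BaseModel):
    gamma_max: PositiveFloat = 40.0
    floor_functional: PositiveFloat = 2.0
    floor_inhibited: PositiveFloat = 25.0
    d50: PositiveFloat = 100.0
    deposition_flux: float = Field(0.0, ge=0)
    compression_exponent: PositiveFloat = 1.0
    noise_sd: float = Field(0.3, ge=0)

    def build(self, seed: int) -> FilmModelParams:
        return FilmModelParams(seed=seed, **self.model_dump())


class RunConfig(BaseModel):
    """Top-level configuration for the CLI workbench."""

    criteria: CriteriaConfig = CriteriaConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    film: FilmConfig = FilmConfig()
    seed: int = 0
    n_replicates: PositiveInt = 4
    out_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (provenance stamp)."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}
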