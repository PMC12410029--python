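"""Run configuration: a validated, fully serialisable description of a run.

A YAML config plus a seed reproduces every output byte-for-byte
(timestamps excluded). Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .aeq_analysis import AEqConfig
from .autoencoder import AutoencoderConfig
from .pipeline import AUDIT_GRID

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Schema of one CLI run."""

    model_config = ConfigDict(extra="forbid")

    cohort: str | None = None
    embeddings: str | None = None
    embeddings_meta: str | None = None
    output_dir: str = "aequity_out"

    grid: list[int] = Field(default_factory=lambda: list(AUDIT_GRID))
    n_boot: int = 50
    epsilon: float | None = None  # None -> relative 0.01 * fitted b
    alpha: float = 0.05
    threshold: float = 0.5
    seed: int = 0
    stratum: int | None = None

    groups: list[str] | None = None  # None -> all groups + joint
    outcomes: list[str] | None = None  # None -> all outcomes

    # curation
    policy: str = "aequity_guided"
    budget: int | None = None

    # simulate
    scenario: str = "none"
    n_per_group: int = 8000
    n_seeds: int = 1
    backend: str = "logistic"

    @field_validator("grid")
    @classmethod
    def _grid_ok(cls, v: list[int]) -> list[int]:
        if len(v) < 4 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("grid must be >= 4 strictly increasing sizes")
        return v

    @field_validator("n_boot")
    @classmethod
    def _boot_ok(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_boot must be >= 1")
        return v

    def aeq_config(self) -> AEqConfig:
        return AEqConfig(
            grid=tuple(self.grid),
            n_boot=self.n_boot,
            epsilon=self.epsilon,
            stratum=self.stratum,
            ae=AutoencoderConfig(),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def provenance(self) -> dict:
        from . import __version__

        return {"config_hash": self.config_hash(), "seed": self.seed, "version": __version__}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
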