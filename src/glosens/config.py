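"""Run configuration: declarative YAML + flag overrides.

Precedence is flags > file > defaults.  Every artifact written by the CLI
embeds the hash of the exact configuration used, so a run can be
reproduced (and is byte-identical when re-run with the same config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from .dynamics import OutputSpec
from .errors import ConfigError
from .fixtures import FIXTURES
from .model import KineticModel
from .swarm import SwarmSettings


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    model: str = "fixture:chain"  # "fixture:<name>" or an SBML file path
    kind: str = "flux"
    target: str = "step1"
    t_end: float = 1000.0
    n_points: int = 4000
    bands: list[float] = field(default_factory=lambda: [0.05, 0.10, 0.25, 0.50])
    n_samples: int = 1000
    seed: int = 0
    rel_step: float = 1e-3
    threshold: float = 1.0
    swarm_size: int = 20
    iteration_limit: int = 100
    chunk_size: int = 1000
    n_bins: int | None = None
    parameters: list[str] | None = None
    outdir: str = "glosens-out"

    def __post_init__(self) -> None:
        if not self.bands or any(b2 <= b1 for b1, b2 in zip(self.bands, self.bands[1:])):
            raise ConfigError("bands must be a non-empty strictly increasing list")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")

    # -- round-trip ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path!r} does not contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def hash(self) -> str:
        """Hash of the analysis-defining fields (the output directory does
        not change what is computed)."""
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        canon = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def stamp(self) -> str:
        """One-line provenance header for text artifacts."""
        return f"config_hash={self.hash()} seed={self.seed}"

    # -- derived objects -------------------------------------------------
    def output_spec(self) -> OutputSpec:
        return OutputSpec(self.kind, self.target, t_end=self.t_end, n_points=self.n_points)

    def swarm_settings(self) -> SwarmSettings:
        return SwarmSettings(
            swarm_size=self.swarm_size,
            iteration_limit=self.iteration_limit,
            seed=self.seed,
        )

    def resolve_model(self) -> KineticModel:
        if self.model.startswith("fixture:"):
            name = self.model.split(":", 1)[1]
            if name not in FIXTURES:
                raise ConfigError(
                    f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
                )
            model, _ = FIXTURES[name]()
            return model
        from .sbml import load_sbml

        return load_sbml(self.model)
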