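"""Run configuration: schema, validation and cross-reference checks.

Configs are YAML or JSON documents validated against a strict pydantic
schema (unknown keys rejected) before any computation runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigurationError

CIRCUIT_KINDS = ("not_gate", "toggle", "ring", "open_ring", "iffl",
                 "double_iffl", "iffl_plus_double_inverter")
TOGGLE_VARIANTS = ("specific_only", "unspecific_neutral", "unspecific_inhibitory")


class CircuitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal[CIRCUIT_KINDS]
    variant: Literal[TOGGLE_VARIANTS] | None = None
    preset: str | None = None
    preset_set: list[str] | None = None
    open_ring: bool = False
    parameter_overrides: dict[str, float] = Field(default_factory=dict)

    @field_validator("parameter_overrides")
    @classmethod
    def _positive(cls, v: dict[str, float]) -> dict[str, float]:
        for name, val in v.items():
            if not val > 0:
                raise ValueError(f"parameter {name!r} must be positive, got {val}")
        return v

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v: str | None) -> str | None:
        if v is not None:
            from .circuits import PRESET_TARGET_FOLD

            if v not in PRESET_TARGET_FOLD:
                raise ValueError(
                    f"unknown sgRNA preset {v!r}; known: {sorted(PRESET_TARGET_FOLD)}"
                )
        return v


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    operations: list[str] = Field(default_factory=list)
    t_end: float = 100.0
    n_starts: int = 12
    dose_grid: list[float] | None = None
    protocol: list[dict] | None = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    circuit: CircuitConfig
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON config file.

    Raises :class:`ConfigurationError` with line context on parse errors
    and field context on schema violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    text = path.read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} must be a mapping at top level")
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        lines = [f"invalid config {path}:"]
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            lines.append(f"  {loc}: {err['msg']}")
        raise ConfigurationError("\n".join(lines)) from exc


def build_circuit(cfg: CircuitConfig):
    """Instantiate the network a validated circuit config describes."""
    from . import circuits

    overrides = cfg.parameter_overrides
    if cfg.kind == "not_gate":
        net = circuits.make_not_gate(cfg.preset or "sg2")
    elif cfg.kind == "toggle":
        net = circuits.make_toggle(cfg.variant or "unspecific_neutral",
                                   overrides or None)
        overrides = {}
    elif cfg.kind in ("ring", "open_ring"):
        net = circuits.make_ring(cfg.kind == "open_ring" or cfg.open_ring,
                                 overrides or None)
        overrides = {}
    elif cfg.kind == "iffl":
        net = circuits.make_iffl(tuple(cfg.preset_set) if cfg.preset_set else "set1")
    elif cfg.kind == "double_iffl":
        a = circuits.make_iffl("set1", prefix="a_")
        b = circuits.make_iffl("set2", prefix="b_")
        net = circuits.compose(a, b, name="double_iffl")
    else:
        raise ConfigurationError(f"circuit kind {cfg.kind!r} has no factory")
    if overrides:
        net.default_params = net.default_params.updated(**overrides)
    return net
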