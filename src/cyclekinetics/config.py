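"""Run configuration: a single JSON/YAML file with a published schema.

Times accept either plain numbers (hours) or an explicit unit object,
``{"hours": 1.5}`` or ``{"minutes": 90}``; minutes are converted at parse
time.  A seed is mandatory for simulation runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import pydantic
from pydantic import BaseModel, Field, field_validator

from .errors import SchemaError
from .types import PhaseDurations, PopulationConfig

__all__ = ["RunConfig", "load_run_config", "config_sha256", "parse_duration"]


def parse_duration(v) -> float:
    """Hours from a number or a {'hours': x} / {'minutes': x} object."""
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return float(v)
    if isinstance(v, dict):
        if set(v) == {"hours"}:
            return float(v["hours"])
        if set(v) == {"minutes"}:
            return float(v["minutes"]) / 60.0
    raise ValueError(
        "durations must be a number (hours) or {'hours': x} / {'minutes': x}"
    )


class PhasesModel(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    t_g1: float
    t_s: float
    t_g2: float
    t_m: float

    @field_validator("t_g1", "t_s", "t_g2", "t_m", mode="before")
    @classmethod
    def _duration(cls, v):
        return parse_duration(v)

    def to_domain(self) -> PhaseDurations:
        return PhaseDurations(self.t_g1, self.t_s, self.t_g2, self.t_m)


class PopulationModel(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    n_cells: int = Field(10_000, ge=1)
    age_distribution: Literal["uniform", "exponential_growth"] = "uniform"
    quit_probability: float = Field(0.0, ge=0.0, le=1.0)
    phase_cv: float = Field(0.0, ge=0.0)
    phh3_g2_fraction: float = Field(0.3, ge=0.0, le=1.0)

    def to_domain(self, seed: int) -> PopulationConfig:
        return PopulationConfig(
            n_cells=self.n_cells,
            age_distribution=self.age_distribution,
            quit_probability=self.quit_probability,
            phase_cv=self.phase_cv,
            phh3_g2_fraction=self.phh3_g2_fraction,
            seed=seed,
        )


class RunConfig(BaseModel):
    """Schema of the ``cckinetics simulate`` / ``recover`` config file."""

    model_config = pydantic.ConfigDict(extra="forbid")

    seed: int
    phases: PhasesModel
    population: PopulationModel = PopulationModel()
    designs: list[str] = Field(default_factory=lambda: [
        "dual-pulse", "g2-timecourse", "mitotic-index", "quit-24h",
    ])
    n_replicates: int = Field(4, ge=1)

    @field_validator("designs")
    @classmethod
    def _known_designs(cls, v):
        from .popsim import DESIGNS

        unknown = [d for d in v if d not in DESIGNS]
        if unknown:
            raise ValueError(
                f"unknown design(s) {unknown}; known: {sorted(DESIGNS)}"
            )
        if not v:
            raise ValueError("at least one design is required")
        return v


def load_run_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Raises :class:`SchemaError` with a field-referenced message on any
    violation (including a missing mandatory seed).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}:{e.lineno}: invalid JSON: {e.msg}") from e
    except Exception as e:  # yaml errors carry their own marks
        raise SchemaError(f"{path}: invalid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except pydantic.ValidationError as e:
        msgs = [
            f"{path}: {'.'.join(str(p) for p in err['loc']) or '<root>'}: "
            f"{err['msg']}"
            for err in e.errors()
        ]
        raise SchemaError("\n".join(msgs)) from e


def config_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
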