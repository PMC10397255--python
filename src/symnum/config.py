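"""Run configuration: JSON schema, validation, and conversion to run objects.

A run is fully described by a JSON document with four blocks — design,
geometry, population, and seeds — validated field-by-field on load.  The
same document is echoed alongside every simulation output so any trial
table can be regenerated exactly.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .experiment import DesignSpec, PopulationParams
from .observer import CONDITIONS, TASKS
from .stimgen import FieldGeometry

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Schema validation failure with field-level messages."""


class _DesignModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    standard_numerosities: list[int] = Field(default=[8, 12, 24, 50], min_length=1)
    conditions: list[str] = Field(default=list(CONDITIONS), min_length=1)
    tasks: list[str] = Field(default=list(TASKS), min_length=1)
    sessions_per_cell: int = Field(default=2, ge=1)
    trials_per_session: int = Field(default=50, ge=1)
    n_participants: int = Field(default=26, ge=1)

    @model_validator(mode="after")
    def _known_levels(self):
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; allowed {CONDITIONS}")
        bad = set(self.tasks) - set(TASKS)
        if bad:
            raise ValueError(f"unknown tasks {sorted(bad)}; allowed {TASKS}")
        if any(n < 2 for n in self.standard_numerosities):
            raise ValueError("standard numerosities must be >= 2")
        return self


class _GeometryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    field_diameter: float = Field(default=10.0, gt=0)
    dot_diameter: float = Field(default=0.3, gt=0)
    min_separation: float = Field(default=0.3, gt=0)
    exclusion_width: float = Field(default=1.6, gt=0)
    exclusion_height: float = Field(default=1.6, gt=0)


class _PopulationModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bias_mean: dict[str, float] = Field(
        default={"ST": 0.9213, "ST_WD": 0.936, "DT": 0.97}
    )
    bias_sd: dict[str, float] = Field(
        default={"ST": 0.045, "ST_WD": 0.042, "DT": 0.025}
    )
    noise_mean: dict[str, float] = Field(
        default={"ST": 0.2096, "ST_WD": 0.2096, "DT": 0.3984}
    )
    noise_sd: dict[str, float] = Field(
        default={"ST": 0.03, "ST_WD": 0.03, "DT": 0.055}
    )
    conj_accuracy_mean: float = Field(default=0.96, ge=0.5, le=1.0)
    conj_accuracy_sd: float = Field(default=0.03, ge=0)
    conj_deficit_mean: float = Field(default=0.02, ge=0)
    conj_deficit_sd: float = Field(default=0.015, ge=0)
    lapse: float = Field(default=0.02, ge=0, le=0.1)

    @model_validator(mode="after")
    def _valid_params(self):
        for task, b in self.bias_mean.items():
            if not 0 < b <= 1.5:
                raise ValueError(f"bias_mean[{task}]={b} outside (0, 1.5]")
        for task, s in self.noise_mean.items():
            if not s > 0:
                raise ValueError(f"noise_mean[{task}]={s} must be > 0")
        for name in ("bias_sd", "noise_sd"):
            for task, sd in getattr(self, name).items():
                if sd < 0:
                    raise ValueError(f"{name}[{task}]={sd} must be >= 0")
        return self


class RunConfig(BaseModel):
    """Validated top-level run configuration."""

    model_config = ConfigDict(extra="forbid")

    design: _DesignModel = Field(default_factory=_DesignModel)
    geometry: _GeometryModel = Field(default_factory=_GeometryModel)
    population: _PopulationModel = Field(default_factory=_PopulationModel)
    master_seed: int = Field(default=0, ge=0)
    output_dir: str | None = None

    @model_validator(mode="after")
    def _population_covers_tasks(self):
        for task in self.design.tasks:
            for block in ("bias_mean", "bias_sd", "noise_mean", "noise_sd"):
                if task not in getattr(self.population, block):
                    raise ValueError(f"population.{block} missing task {task!r}")
        return self

    # -- conversions --------------------------------------------------------
    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            standard_numerosities=tuple(self.design.standard_numerosities),
            conditions=tuple(self.design.conditions),
            tasks=tuple(self.design.tasks),
            sessions_per_cell=self.design.sessions_per_cell,
            trials_per_session=self.design.trials_per_session,
            n_participants=self.design.n_participants,
            seed=self.master_seed,
        )

    def field_geometry(self) -> FieldGeometry:
        return FieldGeometry(**self.geometry.model_dump())

    def population_params(self) -> PopulationParams:
        return PopulationParams(**self.population.model_dump())

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Raises
    ------
    ConfigError
        With one line per offending field when validation fails.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ConfigError(f"not valid JSON: {err}") from err
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as err:
        lines = [
            f"  {'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        ]
        raise ConfigError("invalid configuration:\n" + "\n".join(lines)) from err
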