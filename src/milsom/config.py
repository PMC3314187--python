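"""Run configuration and report models (JSON-serializable, schema-backed)."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .core import Phase, TrainingSchedule, default_schedule
from .grid import SOMGrid
from .pid import PIDGains

__all__ = ["PhaseConfig", "RunConfig", "RunReport", "report_json_schema"]


class PhaseConfig(BaseModel):
    epochs: int = Field(ge=1)
    alpha_start: float = Field(ge=0.0, le=1.0)
    alpha_end: float = Field(ge=0.0, le=1.0)
    radius_start: float = Field(ge=0.0)
    radius_end: float = Field(ge=0.0)

    def to_phase(self) -> Phase:
        return Phase(
            self.epochs, self.alpha_start, self.alpha_end,
            self.radius_start, self.radius_end,
        )


class RunConfig(BaseModel):
    """Everything needed to reproduce a training run, JSON round-trippable."""

    map_rows: int = Field(default=20, ge=1)
    map_cols: int = Field(default=20, ge=1)
    topology: str = "hexagonal"
    kernel: str = "gaussian"
    phases: list[PhaseConfig] | None = None  # None -> schedule derived from map size
    rough_epochs: int = Field(default=10, ge=1)
    fine_epochs: int = Field(default=20, ge=1)
    algorithm: str = "milsom"
    a1: float = Field(default=0.2, ge=0.0)
    a2: float = Field(default=0.05, ge=0.0)
    windup_cap: float | None = None
    normalize: bool = True
    init: str = "random_sample"
    seed: int = 0

    @field_validator("topology")
    @classmethod
    def _topology(cls, v: str) -> str:
        if v not in ("rectangular", "hexagonal"):
            raise ValueError("topology must be 'rectangular' or 'hexagonal'")
        return v

    @field_validator("algorithm")
    @classmethod
    def _algorithm(cls, v: str) -> str:
        if v not in ("standard", "milsom"):
            raise ValueError("algorithm must be 'standard' or 'milsom'")
        return v

    def grid(self) -> SOMGrid:
        return SOMGrid(self.map_rows, self.map_cols, self.topology)

    def schedule(self) -> TrainingSchedule:
        if self.phases is None:
            return default_schedule(
                self.grid(), self.rough_epochs, self.fine_epochs, kernel=self.kernel
            )
        return TrainingSchedule(
            phases=tuple(p.to_phase() for p in self.phases), kernel=self.kernel
        )

    def gains(self) -> PIDGains:
        return PIDGains(self.a1, self.a2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


class QualitySummary(BaseModel):
    quantization_error: float = Field(ge=0.0)
    topographic_error: float = Field(ge=0.0, le=1.0)
    n_records: int = Field(ge=1)


class RunReport(BaseModel):
    """Serialized outcome of one training run."""

    config: RunConfig
    seed: int
    algorithm: str
    epochs: int = Field(ge=1)
    quality: QualitySummary
    j_value: float = Field(ge=0.0)
    qe_history: list[float]
    elapsed_seconds: float | None = None  # informational only


def report_json_schema() -> dict:
    """The JSON schema the shipped ``run_report.schema.json`` is generated from."""
    return RunReport.model_json_schema()
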