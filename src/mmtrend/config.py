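"""Validated run configuration for the pipeline CLI."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class SimulateConfig(BaseModel):
    """Parameters of the synthetic-data generator (see TruthSpec)."""

    n_countries: int = 10
    communities_per_country: int = 5
    start_year: int = 1986
    end_year: int = 2015
    warming_per_decade: float = 0.3
    baseline_deaths: float = 30.0
    overdispersion: float = Field(default=1.5, ge=1.0)
    mmt_offset: float = 6.0
    mmt_slope: float = 0.0
    curvature: float = Field(default=0.004, ge=0.0)
    country_intercept_sd: float = 0.0
    country_slope_sd: float = 0.0
    community_intercept_sd: float = 0.0
    community_slope_sd: float = 0.0


class RunConfig(BaseModel):
    """Everything one end-to-end run needs; serializable to/from YAML."""

    input_dir: str | None = None          # existing dataset; else simulate
    simulate: SimulateConfig = SimulateConfig()
    start_year: int = 1986
    end_year: int = 2015
    subperiod_width: int = Field(default=5, ge=1)
    search_percentiles: tuple[float, float] = (25.0, 99.0)
    n_sim: int = Field(default=1000, ge=2)
    grid_step: float = Field(default=0.1, gt=0.0)
    seed: int = 0
    strata: tuple[str, ...] = ("climate_zone", "region", "country_id")
    metrics: tuple[str, ...] = ("MMT", "MMTP")

    @field_validator("search_percentiles")
    @classmethod
    def _ordered(cls, v):
        if not 0 <= v[0] < v[1] <= 100:
            raise ValueError("search percentiles must be ordered within [0, 100]")
        return v

    @field_validator("metrics")
    @classmethod
    def _metrics(cls, v):
        bad = set(v) - {"MMT", "MMTP"}
        if bad:
            raise ValueError(f"unknown metrics: {sorted(bad)}")
        return v

    @model_validator(mode="after")
    def _window(self):
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.model_validate(data)
        if cfg.input_dir is not None and not Path(cfg.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {cfg.input_dir}")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
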