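"""Run configuration: structured-text (JSON/YAML) loading and validation."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .cohort import CohortConfig
from .costing import UnitCostTable

log = logging.getLogger("depotbia")


class ScenarioConfig(BaseModel):
    label: str = ""
    base_population: int = Field(default=82_000_000, gt=0)
    prevalence: float = Field(gt=0, lt=1)
    market_share: float = Field(default=1.0, ge=0, le=1)


class RunConfig(BaseModel):
    """Everything one pipeline run needs.

    Exactly one cost-input mode must be active: a cohort source (inline
    generator config or a cohort file) for patient-level costing, or a
    component table for published-table mode.
    """

    seed: int = Field(default=20160516, ge=0, lt=2**31)
    locale: str = Field(default="en", pattern="^(en|de)$")
    annualize: bool = False
    output_dir: str = "out"
    productivity_rule: str = "all_days"

    cohort: Optional[CohortConfig] = None
    cohort_file: Optional[str] = None
    component_table: Optional[Union[str, dict]] = None  # path, dict, or "packaged"

    unit_costs: UnitCostTable = Field(default_factory=UnitCostTable)
    scenarios: list[ScenarioConfig] = Field(default_factory=lambda: [
        ScenarioConfig(prevalence=0.008), ScenarioConfig(prevalence=0.009)])
    market_shares: list[float] = Field(default_factory=lambda: [0.04, 0.12])
    sensitivity: Optional[list[dict]] = None  # None -> packaged registry

    @model_validator(mode="after")
    def _one_mode(self) -> "RunConfig":
        cohort_mode = self.cohort is not None or self.cohort_file is not None
        table_mode = self.component_table is not None
        if cohort_mode and table_mode:
            raise ValueError(
                "cohort source and component_table are mutually exclusive; "
                "configure exactly one")
        if not cohort_mode and not table_mode:
            raise ValueError(
                "configure a cost input: either a cohort source "
                "(cohort / cohort_file) or a component_table")
        if self.cohort is not None and self.cohort_file is not None:
            raise ValueError("cohort and cohort_file are mutually exclusive")
        for share in self.market_shares:
            if not 0 <= share <= 1:
                raise ValueError(f"market share {share} outside [0, 1]")
        return self

    @property
    def mode(self) -> str:
        return "component_table" if self.component_table is not None else "cohort"


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a config, embedded in every output file."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a JSON/YAML run configuration.

    Schema violations raise with every offending field listed; loaded
    defaults are echoed to the package logger.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        raise ValueError(f"config file {path} is empty")
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    try:
        config = RunConfig.model_validate(data)
    except ValidationError as err:
        fields = "; ".join(
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors())
        raise ValueError(f"invalid config {path}: {fields}") from err
    log.info("loaded config %s (mode=%s, seed=%d, hash=%s)",
             path, config.mode, config.seed, config_hash(config))
    return config


def default_config() -> RunConfig:
    """Component-table mode against the packaged table — the reproduction
    path for the published results."""
    return RunConfig(component_table="packaged")
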