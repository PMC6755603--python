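"""Orchestration of the full analysis from a validated run configuration."""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import bia, costing, report, sensitivity as sens, stats
from .cohort import generate_cohort, read_cohort, summarize_cohort, validate_utilization
from .config import RunConfig, config_hash

log = logging.getLogger("depotbia")


def resolve_component_table(config: RunConfig) -> costing.ComponentTable:
    """The component table the run operates on, from either input mode."""
    if config.component_table is not None:
        if config.component_table == "packaged":
            return costing.packaged_component_table()
        return costing.load_component_table(config.component_table)
    frame = load_or_generate_cohort(config)
    retained, rejected = validate_utilization(frame)
    if len(rejected):
        log.warning("validate_utilization rejected %d of %d records",
                    len(rejected), len(frame))
    return costing.cost_cohort(retained, config.unit_costs,
                               config.productivity_rule)


def load_or_generate_cohort(config: RunConfig) -> pd.DataFrame:
    if config.cohort_file is not None:
        return read_cohort(config.cohort_file)
    cohort_config = config.cohort
    if cohort_config is None:
        raise ValueError("run config has no cohort source")
    if cohort_config.seed != config.seed:
        cohort_config = cohort_config.model_copy(update={"seed": config.seed})
    return generate_cohort(cohort_config)


def scenarios_from_config(config: RunConfig) -> list[bia.PopulationScenario]:
    return [bia.PopulationScenario(label=s.label,
                                   base_population=s.base_population,
                                   prevalence=s.prevalence,
                                   market_share=s.market_share)
            for s in config.scenarios]


def run_all(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Execute every stage the configuration supports and render reports.

    Returns the results bundle (also written under ``out_dir``).
    """
    bundle: dict = {}
    table = resolve_component_table(config)
    bundle["component_table"] = table

    scenarios = scenarios_from_config(config)
    bundle["bia"] = [bia.compute_savings(table, s, config.annualize)
                     for s in scenarios]
    if config.market_shares:
        bundle["market_share"] = bia.market_share_scenarios(
            table, config.market_shares, scenarios, config.annualize)

    params = (sens.default_parameters(config.unit_costs)
              if config.sensitivity is None
              else [_param_from_dict(d) for d in config.sensitivity])
    results = sens.one_way_analysis(table, params, scenarios)
    bundle["sensitivity"] = results
    bundle["ranking"] = sens.rank_parameters(results)

    if config.mode == "cohort":
        frame = load_or_generate_cohort(config)
        retained, _ = validate_utilization(frame)
        bundle["cohort"] = retained
        bundle["cohort_summary"] = pd.concat(
            {phase: summarize_cohort(retained, phase) for phase in ("a", "b")},
            names=["phase"])
        bundle["endpoints"] = stats.endpoints_frame(stats.endpoint_table(retained))

    if out_dir is not None:
        renderable = {k: v for k, v in bundle.items()
                      if k in ("component_table", "bia", "market_share",
                               "sensitivity", "endpoints", "cohort_summary")}
        report.render_report(renderable, out_dir, locale=config.locale,
                             config_hash=config_hash(config), seed=config.seed)
        if "cohort" in bundle:
            from .cohort import write_cohort
            write_cohort(bundle["cohort"], Path(out_dir) / "cohort.csv")
    return bundle


def _param_from_dict(d: dict) -> sens.SensitivityParameter:
    arms = {arm: sens.ArmVariation(**spec) for arm, spec in d["arms"].items()}
    return sens.SensitivityParameter(
        name=d["name"], mode=d["mode"], linked_category=d["linked_category"],
        arms=arms, base_unit_cost=d.get("base_unit_cost"),
        min_cost=d.get("min_cost"), max_cost=d.get("max_cost"))
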