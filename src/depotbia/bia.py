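"""Budget-impact engine: prevalence-based national extrapolation.

Per-case costs are scaled to a payer population as

    total(arm) = (sample_total(arm) / n) x round(base_population x prevalence)
                 x market_share

The per-case value enters at full precision (never the rounded printed
figure) and patient counts stay fractional under a market share, so the
extrapolation is exactly linear in the patient count.  The analysis is a
single-period (one treatment phase) comparison; an optional ``annualize``
flag doubles the six-month phase costs.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .costing import ComponentTable, ARMS
from .money import round_half_up

Share = Union[float, str, Fraction]


class PopulationScenario(BaseModel):
    """A payer population: base population x prevalence x market share.

    The default base population is the ~82 million German adults aged
    18-65; a prevalence of 0.8-0.9% gives the 656,000-738,000 prevalent
    schizophrenia patients used in national extrapolations.  A market share
    of 1.0 is the (explicitly unrealistic) full-substitution scenario.
    """

    label: str = ""
    base_population: int = Field(default=82_000_000, gt=0)
    prevalence: float = Field(gt=0, lt=1)
    market_share: float = Field(default=1.0, ge=0, le=1)

    @model_validator(mode="after")
    def _label(self) -> "PopulationScenario":
        if not self.label:
            pool = self.prevalent_pool
            share = f", share {self.market_share:.0%}" if self.market_share != 1 else \
                " (100% substitution: unrealistic upper bound)"
            object.__setattr__(self, "label",
                               f"prevalence {self.prevalence:.2%} ({pool:,} patients{share})")
        return self

    @property
    def prevalent_pool(self) -> int:
        """round(base_population x prevalence), as an exact integer."""
        return int(round_half_up(
            Fraction(str(self.prevalence)) * self.base_population, 0))

    @property
    def patient_count(self) -> Fraction:
        """Prevalent pool x market share, kept fractional (not rounded)."""
        return self.prevalent_pool * Fraction(str(self.market_share))


def default_scenarios() -> list[PopulationScenario]:
    """Both published prevalence bounds at full substitution."""
    return [PopulationScenario(prevalence=0.008),
            PopulationScenario(prevalence=0.009)]


@dataclass(frozen=True)
class BudgetImpactResult:
    """Cost of each arm under one scenario and the implied savings."""

    scenario: PopulationScenario
    cost_oral: Decimal
    cost_depot: Decimal
    savings: Decimal
    per_case_savings: Decimal


def _extrapolate_cents(table: ComponentTable, arm: str,
                       scenario: PopulationScenario,
                       annualize: bool = False) -> Fraction:
    if table.n == 0:
        raise ValueError("component table has n = 0")
    cents = table.per_case_total_cents(arm) * scenario.patient_count
    return cents * 2 if annualize else cents


def extrapolate_total_cost(table: ComponentTable, arm: str,
                           scenario: PopulationScenario,
                           annualize: bool = False) -> Decimal:
    """Population-scale total cost of one arm, in euros (2 decimals)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    return round_half_up(_extrapolate_cents(table, arm, scenario, annualize) / 100)


def compute_savings(table: ComponentTable, scenario: PopulationScenario,
                    annualize: bool = False) -> BudgetImpactResult:
    """Budget impact (oral minus depot) of switching under one scenario."""
    oral = extrapolate_total_cost(table, "oral", scenario, annualize)
    depot = extrapolate_total_cost(table, "depot", scenario, annualize)
    pc = table.per_case_total_cents("oral") - table.per_case_total_cents("depot")
    if annualize:
        pc *= 2
    return BudgetImpactResult(
        scenario=scenario, cost_oral=oral, cost_depot=depot,
        savings=oral - depot, per_case_savings=round_half_up(pc / 100))


def market_share_scenarios(table: ComponentTable, shares: Sequence[float],
                           scenarios: Sequence[PopulationScenario],
                           annualize: bool = False) -> pd.DataFrame:
    """One row per (market share x prevalence scenario), both arms costed.

    Costs are monotone non-decreasing in the share by linearity.
    """
    shares = list(shares)
    if not shares:
        raise ValueError("at least one market share is required")
    for s in shares:
        if not 0 <= float(s) <= 1:
            raise ValueError(f"market share {s} outside [0, 1]")
    rows = []
    for base in scenarios:
        for share in shares:
            scen = PopulationScenario(
                base_population=base.base_population,
                prevalence=base.prevalence, market_share=float(share))
            result = compute_savings(table, scen, annualize)
            rows.append({
                "prevalence": base.prevalence,
                "prevalent_pool": scen.prevalent_pool,
                "market_share": float(share),
                "patient_count": float(scen.patient_count),
                "cost_oral_eur": result.cost_oral,
                "cost_depot_eur": result.cost_depot,
                "savings_eur": result.savings,
            })
    return pd.DataFrame(rows)
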