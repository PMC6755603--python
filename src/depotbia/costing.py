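"""Per-patient costing and cost aggregation across 13 resource categories.

Costs are assessed from the payer perspective of the German statutory health
insurance (GKV) over one six-month treatment phase.  Priced quantities
(days, contacts, injections) are multiplied by unit rates; fee-schedule
services (EBM for statutory, GOÄ for private insurance) and medication
spending enter as euro pass-through amounts.  Productivity losses from sick
leave are the only indirect-cost category.

Two entry modes feed the downstream budget-impact and sensitivity stages:

* *patient-level mode* — cost a (synthetic) cohort record by record;
* *component-table mode* — load a published per-case/sample component table
  directly; this is the canonical path for reproducing reported results,
  since category-level means cannot always be reconciled with utilization
  means in the underlying publication.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .cohort import PatientRecord, records_from_frame
from .money import cents_to_eur, round_half_up, to_cents

#: the 13 cost categories, in reporting order
CATEGORIES = (
    "productivity_loss",
    "ebm_services",
    "goa_services",
    "day_clinic_pia",
    "ebm_inpatient",
    "goa_inpatient",
    "hospital_days",
    "emergency_services",
    "emergency_physician",
    "non_drug_interventions",
    "depot_injections",
    "medication",
    "comorbid_medication",
)

#: categories counted as indirect costs (productivity losses)
INDIRECT_CATEGORIES = ("productivity_loss",)

ARMS = ("oral", "depot")

SCOPES = ("per_patient", "per_case", "sample_total", "population_total")


class UnitCostTable(BaseModel):
    """Unit prices in euros, with admissible ranges where sources give one.

    Day-clinic/PIA and hospital per-diems are published as ranges; the base
    rate defaults to the range midpoint and can be overridden.
    """

    sick_leave_day_eur: float = Field(default=90.0, ge=0)
    day_clinic_day_eur: float = Field(default=240.0, ge=0)
    day_clinic_range_eur: tuple[float, float] = (120.0, 360.0)
    hospital_day_eur: float = Field(default=237.50, ge=0)
    hospital_day_range_eur: tuple[float, float] = (90.0, 385.0)
    emergency_service_eur: float = Field(default=13.37, ge=0)
    emergency_physician_eur: float = Field(default=171.0, ge=0)
    depot_injection_eur: float = Field(default=515.97, ge=0)

    @model_validator(mode="after")
    def _check_ranges(self) -> "UnitCostTable":
        for base, rng, name in (
                (self.day_clinic_day_eur, self.day_clinic_range_eur, "day_clinic"),
                (self.hospital_day_eur, self.hospital_day_range_eur, "hospital_day")):
            lo, hi = rng
            if not (0 <= lo <= base <= hi):
                raise ValueError(
                    f"{name}: base rate {base} must lie inside the range [{lo}, {hi}]")
        return self


#: named presets for the two published day-clinic/PIA per-diem ranges
DAY_CLINIC_PRESETS: dict[str, tuple[float, float]] = {
    "bag_psych": (120.0, 360.0),        # fee-negotiation corridor
    "sensitivity": (240.0, 720.0),      # range used for cost-uncertainty runs
}


# productivity rules: raw sick-leave days -> cost-relevant days.  Under the
# German sickness-benefit rule the insurer pays only from the 7th week
# (employers cover the first 42 days of a continuous spell).
PRODUCTIVITY_RULES: dict[str, Callable[[float], float]] = {
    "all_days": lambda days: days,
    "sickness_benefit": lambda days: max(0.0, days - 42.0),
}


@dataclass(frozen=True)
class CostBreakdown:
    """Euro cents per category, at a stated scope, optionally for one arm."""

    values: Mapping[str, int]
    scope: str = "per_patient"
    arm: Optional[str] = None

    def __post_init__(self):
        got = set(self.values)
        expected = set(CATEGORIES)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            parts = []
            if missing:
                parts.append(f"missing categories: {missing}")
            if extra:
                parts.append(f"unknown categories: {extra}")
            raise ValueError("; ".join(parts))
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("cost categories must be non-negative")

    @property
    def total_cents(self) -> int:
        return sum(self.values.values())

    def category_eur(self, category: str) -> Decimal:
        return cents_to_eur(self.values[category])

    def total_eur(self) -> Decimal:
        return cents_to_eur(self.total_cents)

    def scaled(self, factor: int, scope: str) -> "CostBreakdown":
        return CostBreakdown({c: v * factor for c, v in self.values.items()},
                             scope=scope, arm=self.arm)


def zero_breakdown(scope: str = "per_patient", arm: Optional[str] = None
                   ) -> CostBreakdown:
    return CostBreakdown({c: 0 for c in CATEGORIES}, scope=scope, arm=arm)


def compute_patient_phase_cost(record: PatientRecord, phase: str,
                               unit_costs: UnitCostTable,
                               productivity_rule: str = "all_days"
                               ) -> CostBreakdown:
    """Cost one patient-phase: quantities x unit rates plus pass-through €.

    ``productivity_rule`` maps raw sick-leave days to cost-relevant days
    (``all_days`` or ``sickness_benefit``).
    """
    try:
        rule = PRODUCTIVITY_RULES[productivity_rule]
    except KeyError:
        raise ValueError(
            f"unknown productivity_rule {productivity_rule!r}; "
            f"expected one of {sorted(PRODUCTIVITY_RULES)}") from None
    u = record.phase(phase)
    uc = unit_costs
    eur = {
        "productivity_loss": rule(u.sick_leave_days) * uc.sick_leave_day_eur,
        "ebm_services": u.ebm_outpatient_eur,
        "goa_services": u.goa_outpatient_eur,
        "day_clinic_pia": u.day_clinic_days * uc.day_clinic_day_eur,
        "ebm_inpatient": u.ebm_inpatient_eur,
        "goa_inpatient": u.goa_inpatient_eur,
        "hospital_days": u.hospital_days * uc.hospital_day_eur,
        "emergency_services": u.emergency_service_contacts * uc.emergency_service_eur,
        "emergency_physician": u.emergency_physician_contacts * uc.emergency_physician_eur,
        "non_drug_interventions": u.non_drug_eur,
        "depot_injections": u.depot_injections * uc.depot_injection_eur,
        "medication": u.medication_eur,
        "comorbid_medication": u.comorbid_medication_eur,
    }
    return CostBreakdown({c: to_cents(float(v)) for c, v in eur.items()},
                         scope="per_patient")


# ---------------------------------------------------------------------------
# component table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentTable:
    """Per-case cost components for both arms, held exactly.

    Internally each category is an exact rational number of cents at
    *per-case* scale (sample totals divided by ``n`` stay exact), so the
    per-case, sample and population scales are consistent by construction.
    """

    per_case_cents: Mapping[str, Mapping[str, Fraction]]  # arm -> category -> cents
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if set(self.per_case_cents) != set(ARMS):
            raise ValueError(f"component table needs arms {ARMS}")
        for arm in ARMS:
            got = set(self.per_case_cents[arm])
            if got != set(CATEGORIES):
                missing = sorted(set(CATEGORIES) - got)
                extra = sorted(got - set(CATEGORIES))
                raise ValueError(
                    f"arm {arm!r}: missing categories {missing}, unknown {extra}")

    # exact accessors ----------------------------------------------------
    def per_case_category_cents(self, arm: str, category: str) -> Fraction:
        return self.per_case_cents[arm][category]

    def per_case_total_cents(self, arm: str) -> Fraction:
        return sum(self.per_case_cents[arm].values(), Fraction(0))

    def sample_total_cents(self, arm: str, category: Optional[str] = None) -> Fraction:
        if category is None:
            return self.per_case_total_cents(arm) * self.n
        return self.per_case_cents[arm][category] * self.n

    # presentation -------------------------------------------------------
    def per_case_eur(self, arm: str, category: str) -> Decimal:
        return round_half_up(self.per_case_cents[arm][category] / 100)

    def per_case_total_eur(self, arm: str) -> Decimal:
        return round_half_up(self.per_case_total_cents(arm) / 100)

    def sample_total_eur(self, arm: str, category: Optional[str] = None) -> Decimal:
        return round_half_up(self.sample_total_cents(arm, category) / 100)

    def breakdown(self, arm: str, scope: str = "per_case") -> CostBreakdown:
        """Rounded integer-cent view of one arm at per-case or sample scale."""
        if scope == "per_case":
            vals = {c: int(round_half_up(v, 0))
                    for c, v in self.per_case_cents[arm].items()}
        elif scope == "sample_total":
            vals = {c: int(round_half_up(v * self.n, 0))
                    for c, v in self.per_case_cents[arm].items()}
        else:
            raise ValueError(f"unsupported scope {scope!r}")
        return CostBreakdown(vals, scope=scope, arm=arm)

    def with_category(self, arm: str, category: str, cents: Fraction
                      ) -> "ComponentTable":
        if cents < 0:
            raise ValueError("cost categories must be non-negative")
        new_arm = dict(self.per_case_cents[arm])
        new_arm[category] = Fraction(cents)
        per_case = dict(self.per_case_cents)
        per_case[arm] = new_arm
        return ComponentTable(per_case, self.n)

    def to_dict(self, scope: str = "sample_total") -> dict:
        if scope not in ("per_case", "sample_total"):
            raise ValueError(f"unsupported scope {scope!r}")
        factor = self.n if scope == "sample_total" else 1
        return {
            "n": self.n,
            "scope": scope,
            "arms": {arm: {c: str(round_half_up(v * factor / 100))
                           for c, v in self.per_case_cents[arm].items()}
                     for arm in ARMS},
        }


def aggregate_costs(breakdowns_by_arm: Mapping[str, Sequence[CostBreakdown]],
                    n: Optional[int] = None
                    ) -> tuple[ComponentTable, dict[str, CostBreakdown]]:
    """Aggregate per-patient breakdowns into a component table and exact
    sample totals.

    ``n`` defaults to the number of breakdowns per arm; per-case values are
    sample totals divided by ``n`` (kept exact), so
    ``per_case * n == sample_total`` for every category.
    """
    missing = set(ARMS) - set(breakdowns_by_arm)
    if missing:
        raise ValueError(f"missing arms: {sorted(missing)}")
    totals: dict[str, CostBreakdown] = {}
    per_case: dict[str, dict[str, Fraction]] = {}
    for arm in ARMS:
        items = list(breakdowns_by_arm[arm])
        if not items:
            raise ValueError(f"arm {arm!r}: no breakdowns to aggregate")
        size = n if n is not None else len(items)
        if size < 1:
            raise ValueError("n must be >= 1")
        summed = {c: sum(b.values[c] for b in items) for c in CATEGORIES}
        totals[arm] = CostBreakdown(summed, scope="sample_total", arm=arm)
        per_case[arm] = {c: Fraction(v, size) for c, v in summed.items()}
    sizes = {len(breakdowns_by_arm[arm]) for arm in ARMS}
    size = n if n is not None else sizes.pop()
    return ComponentTable(per_case, size), totals


def cost_cohort(frame, unit_costs: UnitCostTable,
                productivity_rule: str = "all_days") -> ComponentTable:
    """Patient-level costing of a cohort table: phase A is costed as the
    oral arm and phase B as the depot arm."""
    records = records_from_frame(frame)
    by_arm = {
        "oral": [compute_patient_phase_cost(r, "a", unit_costs, productivity_rule)
                 for r in records],
        "depot": [compute_patient_phase_cost(r, "b", unit_costs, productivity_rule)
                  for r in records],
    }
    table, _ = aggregate_costs(by_arm)
    return table


def load_component_table(source: Union[str, Path, Mapping]) -> ComponentTable:
    """Load a component table from structured text (JSON/YAML) or a mapping.

    Expected layout::

        {"n": 132, "scope": "sample_total",
         "arms": {"oral": {<category>: <euros>, ...}, "depot": {...}}}

    ``scope`` may be ``sample_total`` or ``per_case``.  Validation names
    every missing or unknown category.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("component table must be a mapping")
    for key in ("n", "arms"):
        if key not in data:
            raise ValueError(f"component table lacks required key {key!r}")
    n = int(data["n"])
    scope = data.get("scope", "sample_total")
    if scope not in ("per_case", "sample_total"):
        raise ValueError(f"unsupported component-table scope {scope!r}")
    arms = data["arms"]
    if set(arms) != set(ARMS):
        raise ValueError(f"component table needs arms {ARMS}, got {sorted(arms)}")
    per_case: dict[str, dict[str, Fraction]] = {}
    for arm in ARMS:
        cats = arms[arm]
        missing = sorted(set(CATEGORIES) - set(cats))
        extra = sorted(set(cats) - set(CATEGORIES))
        if missing or extra:
            raise ValueError(
                f"arm {arm!r}: missing categories {missing}, unknown {extra}")
        cents = {c: to_cents(cats[c]) for c in CATEGORIES}
        if scope == "sample_total":
            per_case[arm] = {c: Fraction(v, n) for c, v in cents.items()}
        else:
            per_case[arm] = {c: Fraction(v) for c, v in cents.items()}
    return ComponentTable(per_case, n)


def packaged_component_table() -> ComponentTable:
    """The component table shipped with the package (sample totals, n=132)."""
    with resources.files("depotbia.data").joinpath("component_table.json").open() as fh:
        return load_component_table(json.load(fh))


def write_component_table(table: ComponentTable, path,
                          scope: str = "sample_total") -> None:
    Path(path).write_text(json.dumps(table.to_dict(scope), indent=2) + "\n")


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def split_direct_indirect(breakdown: CostBreakdown
                          ) -> tuple[Decimal, Decimal, Decimal]:
    """(direct €, indirect €, total €) of a breakdown.

    Indirect costs are productivity losses; direct = total − indirect,
    so the three always reconcile exactly.
    """
    indirect = sum(breakdown.values[c] for c in INDIRECT_CATEGORIES)
    total = breakdown.total_cents
    return cents_to_eur(total - indirect), cents_to_eur(indirect), cents_to_eur(total)


def split_direct_indirect_per_case(table: ComponentTable, arm: str
                                   ) -> tuple[Decimal, Decimal, Decimal]:
    """Exact per-case direct/indirect/total split for one arm."""
    indirect = sum((table.per_case_cents[arm][c] for c in INDIRECT_CATEGORIES),
                   Fraction(0))
    total = table.per_case_total_cents(arm)
    return (round_half_up((total - indirect) / 100),
            round_half_up(indirect / 100),
            round_half_up(total / 100))


def medication_share(table: ComponentTable, arm: str, sub_component_eur,
                     category: str = "medication") -> float:
    """Share of one sub-component (e.g. a single drug's spending) within a
    cost category, as a proportion."""
    sub_cents = to_cents(sub_component_eur)
    value = table.per_case_category_cents(arm, category)
    if sub_cents == 0:
        return 0.0
    if value == 0:
        raise ValueError(
            f"category {category!r} is zero but sub-component is {sub_component_eur}")
    if sub_cents > value:
        raise ValueError(
            f"sub-component {sub_component_eur} exceeds the {category!r} value "
            f"{float(value) / 100:.2f}")
    return float(Fraction(sub_cents) / value)
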