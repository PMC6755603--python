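"""One-way (univariate) deterministic sensitivity analysis.

One parameter is moved to its lower or upper bound while every other
parameter stays at base value.  Occurrence-type parameters (days, contacts)
are varied by one standard deviation around the mean, truncated at zero;
unit-cost parameters move across their published price range.  The linked
cost component is rescaled proportionally:

    component' = component x varied_value / base_value

which keeps the untouched 12 categories fixed and reproduces the published
productivity-loss and hospital-day sensitivity cells exactly.  Parameters
are ranked by the per-case cost range (max - min) they induce.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from typing import Literal, Mapping, Optional, Sequence

from .bia import PopulationScenario, extrapolate_total_cost
from .costing import ARMS, CATEGORIES, ComponentTable, UnitCostTable
from .money import round_half_up

Direction = Literal["min", "max"]


def truncated_bounds(mean: float, sd: float) -> tuple[float, float]:
    """(mean - sd, mean + sd), with the lower bound truncated at zero."""
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    return max(mean - sd, 0.0), mean + sd


@dataclass(frozen=True)
class ArmVariation:
    """Base mean and spread of one varied quantity in one arm.

    Explicit ``min_value``/``max_value`` override the mean +/- SD bounds
    (publications sometimes print floored bounds).
    """

    base_mean: float
    sd: float = 0.0
    min_value: Optional[float] = None
    max_value: Optional[float] = None

    def bounds(self) -> tuple[float, float]:
        lo, hi = truncated_bounds(self.base_mean, self.sd)
        if self.min_value is not None:
            lo = self.min_value
        if self.max_value is not None:
            hi = self.max_value
        if lo < 0:
            raise ValueError("lower bound must be non-negative")
        return lo, hi


@dataclass(frozen=True)
class SensitivityParameter:
    """One uncertain quantity: either an occurrence probability/mean
    (``probability`` mode) or a unit price (``cost`` mode), linked to a
    single cost category."""

    name: str
    mode: Literal["probability", "cost"]
    linked_category: str
    arms: Mapping[str, ArmVariation]
    # cost mode only; a base of None means "implied rate": the per-case
    # component divided by the arm's base mean quantity
    base_unit_cost: Optional[float] = None
    min_cost: Optional[float] = None
    max_cost: Optional[float] = None

    def __post_init__(self):
        if self.linked_category not in CATEGORIES:
            raise ValueError(f"unknown linked_category {self.linked_category!r}")
        if self.mode == "cost" and (self.min_cost is None or self.max_cost is None):
            raise ValueError(f"{self.name}: cost mode requires min_cost and max_cost")


@dataclass(frozen=True)
class SensitivityResult:
    """Per-case and sample cost of one arm with one parameter at one bound."""

    parameter: str
    direction: str  # 'min', 'max' or 'base'
    arm: str
    per_case_eur: Decimal
    sample_total_eur: Decimal
    table: ComponentTable
    population_eur: Mapping[str, Decimal] = field(default_factory=dict)


def _ratio(varied: float, base: float, name: str) -> Fraction:
    if base == 0:
        if varied == 0:
            return Fraction(0)
        raise ValueError(f"{name}: base value is 0 but varied value is {varied}")
    return Fraction(str(varied)) / Fraction(str(base))


def vary_parameter(table: ComponentTable, param: SensitivityParameter,
                   direction: Direction, arm: str) -> SensitivityResult:
    """Rebuild the component table with one parameter at one bound.

    Probability mode rescales the linked component by varied/base mean;
    cost mode rescales by varied/base unit price.  Exactly one category
    changes; the per-case total is recomputed from the exact table.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if direction not in ("min", "max"):
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    spec = param.arms[arm]
    lo, hi = spec.bounds()
    varied = lo if direction == "min" else hi
    if param.mode == "probability":
        ratio = _ratio(varied, spec.base_mean, param.name)
    else:
        base_cost = param.base_unit_cost
        if base_cost is None:
            # implied per-unit rate from the table itself
            if spec.base_mean == 0:
                raise ValueError(
                    f"{param.name}: implied unit cost needs a non-zero base mean")
            component = table.per_case_category_cents(arm, param.linked_category)
            implied = component / Fraction(str(spec.base_mean)) / 100  # € per unit
            cost = param.min_cost if direction == "min" else param.max_cost
            ratio = Fraction(str(cost)) / implied
        else:
            cost = param.min_cost if direction == "min" else param.max_cost
            ratio = _ratio(cost, base_cost, param.name)
    base_component = table.per_case_category_cents(arm, param.linked_category)
    varied_table = table.with_category(arm, param.linked_category,
                                       base_component * ratio)
    return SensitivityResult(
        parameter=param.name, direction=direction, arm=arm,
        per_case_eur=varied_table.per_case_total_eur(arm),
        sample_total_eur=varied_table.sample_total_eur(arm),
        table=varied_table)


def _with_population(result: SensitivityResult,
                     scenarios: Sequence[PopulationScenario]
                     ) -> SensitivityResult:
    pops = {s.label: extrapolate_total_cost(result.table, result.arm, s)
            for s in scenarios}
    return SensitivityResult(**{**result.__dict__, "population_eur": pops})


def one_way_analysis(table: ComponentTable,
                     params: Sequence[SensitivityParameter],
                     scenarios: Sequence[PopulationScenario] = ()
                     ) -> list[SensitivityResult]:
    """Full univariate analysis: a base-case reference row per arm, then
    min/max rows per parameter and arm, each extrapolated to every scenario."""
    if not params:
        raise ValueError("at least one sensitivity parameter is required")
    names = [p.name for p in params]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate parameter names: {dupes}")
    results: list[SensitivityResult] = []
    for arm in ARMS:
        base = SensitivityResult(
            parameter="base_case", direction="base", arm=arm,
            per_case_eur=table.per_case_total_eur(arm),
            sample_total_eur=table.sample_total_eur(arm), table=table)
        results.append(_with_population(base, scenarios))
    for param in params:
        for arm in ARMS:
            for direction in ("min", "max"):
                res = vary_parameter(table, param, direction, arm)
                results.append(_with_population(res, scenarios))
    return results


def rank_parameters(results: Sequence[SensitivityResult]) -> list[str]:
    """Parameter names ordered by decreasing per-case cost range.

    The range is max - min per arm; a parameter's score is its largest
    range across arms.  Requires both directions for every parameter.
    """
    by_param: dict[str, dict[str, dict[str, Decimal]]] = {}
    for r in results:
        if r.direction == "base":
            continue
        by_param.setdefault(r.parameter, {}).setdefault(r.arm, {})[r.direction] = \
            r.per_case_eur
    ranges: dict[str, Decimal] = {}
    for name, arms in by_param.items():
        best = Decimal(0)
        for arm, dirs in arms.items():
            if set(dirs) != {"min", "max"}:
                raise ValueError(
                    f"parameter {name!r} (arm {arm!r}) lacks a direction: "
                    f"have {sorted(dirs)}")
            best = max(best, abs(dirs["max"] - dirs["min"]))
        ranges[name] = best
    return sorted(ranges, key=lambda n: ranges[n], reverse=True)


def default_parameters(unit_costs: Optional[UnitCostTable] = None,
                       day_clinic_cost_preset: str = "sensitivity"
                       ) -> list[SensitivityParameter]:
    """The seven published uncertain parameters: five occurrence quantities
    varied by mean +/- SD (explicit printed bounds kept where the source
    floors them at zero) and two per-diem prices varied across their ranges.
    """
    uc = unit_costs or UnitCostTable()
    from .costing import DAY_CLINIC_PRESETS
    dc_lo, dc_hi = DAY_CLINIC_PRESETS[day_clinic_cost_preset]
    return [
        SensitivityParameter(
            name="productivity_loss_days", mode="probability",
            linked_category="productivity_loss",
            arms={"oral": ArmVariation(40.06, 29.62, 10.44, 69.68),
                  "depot": ArmVariation(15.80, 24.67, 0.00, 40.47)}),
        SensitivityParameter(
            name="day_clinic_days", mode="probability",
            linked_category="day_clinic_pia",
            arms={"oral": ArmVariation(46.13, 45.47, 0.66, 91.6),
                  "depot": ArmVariation(7.29, 15.02, 0.00, 22.31)}),
        SensitivityParameter(
            name="hospital_days", mode="probability",
            linked_category="hospital_days",
            arms={"oral": ArmVariation(27.39, 41.37, 0.00, 68.76),
                  "depot": ArmVariation(5.56, 20.70, 0.00, 26.26)}),
        SensitivityParameter(
            name="emergency_physician_contacts", mode="probability",
            linked_category="emergency_physician",
            arms={"oral": ArmVariation(1.42, 0.79, 0.00, 2.21),
                  "depot": ArmVariation(2.00, 1.00, 0.00, 3.00)}),
        SensitivityParameter(
            name="emergency_service_contacts", mode="probability",
            linked_category="emergency_services",
            arms={"oral": ArmVariation(2.38, 2.53, 0.00, 4.91),
                  "depot": ArmVariation(2.00, 1.00, 0.00, 3.00)}),
        SensitivityParameter(
            name="day_clinic_unit_cost", mode="cost",
            linked_category="day_clinic_pia",
            arms={"oral": ArmVariation(46.13), "depot": ArmVariation(7.29)},
            base_unit_cost=(dc_lo + dc_hi) / 2, min_cost=dc_lo, max_cost=dc_hi),
        SensitivityParameter(
            name="hospital_day_unit_cost", mode="cost",
            linked_category="hospital_days",
            arms={"oral": ArmVariation(27.39), "depot": ArmVariation(5.56)},
            base_unit_cost=None,  # implied rate per arm
            min_cost=uc.hospital_day_range_eur[0],
            max_cost=uc.hospital_day_range_eur[1]),
    ]
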