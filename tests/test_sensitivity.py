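"""One-way sensitivity analysis: bounds, ratio scaling, ranking."""
from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from depotbia import (ArmVariation, SensitivityParameter, default_parameters,
                      one_way_analysis, rank_parameters, truncated_bounds,
                      vary_parameter)
from depotbia.costing import CATEGORIES


@pytest.fixture(scope="module")
def params():
    return {p.name: p for p in default_parameters()}


class TestTruncatedBounds:
    @pytest.mark.parametrize("mean, sd, expected", [
        (27.39, 41.37, (0.0, 68.76)),        # lower bound truncated at zero
        (40.06, 29.62, (10.44, 69.68)),
        (5.0, 0.0, (5.0, 5.0)),
    ])
    def test_mean_plus_minus_sd_with_zero_floor(self, mean, sd, expected):
        lo, hi = truncated_bounds(mean, sd)
        assert lo == pytest.approx(expected[0], abs=1e-9)
        assert hi == pytest.approx(expected[1], abs=1e-9)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            truncated_bounds(1.0, -0.1)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_bounds_bracket_the_mean_and_stay_nonnegative(self, mean, sd):
        lo, hi = truncated_bounds(mean, sd)
        assert 0 <= lo <= mean <= hi


class TestVaryParameter:
    @pytest.mark.parametrize("name, direction, arm, expected", [
        ("productivity_loss_days", "max", "oral", "10258.50"),
        ("productivity_loss_days", "min", "oral", "9612.25"),
        ("hospital_days", "min", "oral", "4282.58"),
        ("hospital_days", "max", "oral", "18473.38"),
        ("hospital_days", "min", "depot", "3269.52"),
        ("hospital_days", "max", "depot", "9352.96"),
    ])
    def test_reproduces_published_cells(self, component_table, params,
                                        name, direction, arm, expected):
        result = vary_parameter(component_table, params[name], direction, arm)
        assert abs(result.per_case_eur - Decimal(expected)) <= Decimal("0.10")

    def test_hospital_days_min_removes_the_whole_component(self, component_table,
                                                           params):
        result = vary_parameter(component_table, params["hospital_days"],
                                "min", "depot")
        expected = component_table.per_case_total_cents("depot") \
            - component_table.per_case_category_cents("depot", "hospital_days")
        assert result.table.per_case_total_cents("depot") == expected

    def test_varying_to_base_recovers_base_case_to_the_cent(self, component_table):
        param = SensitivityParameter(
            name="identity", mode="probability", linked_category="hospital_days",
            arms={"oral": ArmVariation(27.39, 0.0), "depot": ArmVariation(5.56, 0.0)})
        for arm in ("oral", "depot"):
            for direction in ("min", "max"):
                result = vary_parameter(component_table, param, direction, arm)
                assert result.table.per_case_total_cents(arm) == \
                    component_table.per_case_total_cents(arm)

    def test_single_touch_property(self, component_table, params):
        result = vary_parameter(component_table, params["productivity_loss_days"],
                                "max", "oral")
        changed = [c for c in CATEGORIES
                   if result.table.per_case_cents["oral"][c]
                   != component_table.per_case_cents["oral"][c]]
        assert changed == ["productivity_loss"]
        assert result.table.per_case_cents["depot"] == \
            component_table.per_case_cents["depot"]

    def test_monotone_in_varied_value(self, component_table):
        per_case = []
        for varied in (10.0, 27.39, 50.0, 68.76):
            param = SensitivityParameter(
                name="probe", mode="probability", linked_category="hospital_days",
                arms={"oral": ArmVariation(27.39, 0.0, varied, varied),
                      "depot": ArmVariation(5.56, 0.0)})
            per_case.append(vary_parameter(component_table, param, "max",
                                           "oral").per_case_eur)
        assert per_case == sorted(per_case)

    def test_zero_base_mean_with_nonzero_bound_errors(self, component_table):
        param = SensitivityParameter(
            name="bad", mode="probability", linked_category="hospital_days",
            arms={"oral": ArmVariation(0.0, 0.0, 0.0, 5.0)})
        with pytest.raises(ValueError, match="base"):
            vary_parameter(component_table, param, "max", "oral")

    def test_cost_mode_uses_price_ratio(self, component_table):
        param = SensitivityParameter(
            name="day_clinic_price", mode="cost", linked_category="day_clinic_pia",
            arms={"oral": ArmVariation(46.13), "depot": ArmVariation(7.29)},
            base_unit_cost=480.0, min_cost=240.0, max_cost=720.0)
        result = vary_parameter(component_table, param, "min", "oral")
        base_comp = component_table.per_case_category_cents("oral", "day_clinic_pia")
        assert result.table.per_case_category_cents("oral", "day_clinic_pia") == \
            base_comp * Fraction(1, 2)


class TestOneWayAnalysis:
    def test_row_count_and_base_reference(self, component_table, params):
        results = one_way_analysis(component_table, list(params.values()))
        # 2 base rows + 7 parameters x 2 arms x 2 directions
        assert len(results) == 2 + 7 * 2 * 2
        base = [r for r in results if r.direction == "base"]
        assert {r.arm for r in base} == {"oral", "depot"}
        oral_base = next(r for r in base if r.arm == "oral")
        assert oral_base.per_case_eur == Decimal("9935.38")

    def test_population_columns_follow_scenarios(self, component_table, params):
        from depotbia import PopulationScenario
        scen = PopulationScenario(prevalence=0.008)
        results = one_way_analysis(component_table, list(params.values()), [scen])
        for r in results:
            assert list(r.population_eur) == [scen.label]
            # cross-scale consistency: population figure = per-case x count
            per_case_cents = r.table.per_case_total_cents(r.arm)
            expected = float(per_case_cents * scen.patient_count) / 100
            assert float(r.population_eur[scen.label]) == pytest.approx(
                expected, abs=0.01)

    def test_empty_scenarios_produce_no_population_columns(self, component_table,
                                                           params):
        results = one_way_analysis(component_table, list(params.values()))
        assert all(r.population_eur == {} for r in results)

    def test_duplicate_parameter_names_rejected(self, component_table, params):
        twice = [params["hospital_days"], params["hospital_days"]]
        with pytest.raises(ValueError, match="duplicate"):
            one_way_analysis(component_table, twice)

    def test_empty_parameter_list_rejected(self, component_table):
        with pytest.raises(ValueError, match="parameter"):
            one_way_analysis(component_table, [])


class TestRanking:
    def test_hospital_days_first_emergency_last(self, component_table, params):
        results = one_way_analysis(component_table, list(params.values()))
        ranking = rank_parameters(results)
        assert ranking[0] == "hospital_days"
        assert set(ranking[-2:]) == {"emergency_physician_contacts",
                                     "emergency_service_contacts"}

    def test_single_parameter_ranks_itself(self, component_table, params):
        results = one_way_analysis(component_table, [params["hospital_days"]])
        assert rank_parameters(results) == ["hospital_days"]

    def test_missing_direction_errors(self, component_table, params):
        result = vary_parameter(component_table, params["hospital_days"],
                                "min", "oral")
        with pytest.raises(ValueError, match="direction"):
            rank_parameters([result])
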