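"""Costing: unit pricing, exact aggregation, component-table handling."""
from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from depotbia import (CATEGORIES, UnitCostTable, aggregate_costs,
                      compute_patient_phase_cost, load_component_table,
                      medication_share, split_direct_indirect,
                      split_direct_indirect_per_case)
from depotbia.costing import (CostBreakdown, write_component_table,
                              zero_breakdown)
from depotbia.money import fmt_eur, parse_eur, to_cents

from conftest import make_patient


class TestPatientPhaseCost:
    def test_all_zero_utilization_costs_nothing(self, unit_costs):
        cost = compute_patient_phase_cost(make_patient(), "a", unit_costs)
        assert cost.total_cents == 0
        assert all(v == 0 for v in cost.values.values())

    @pytest.mark.parametrize("fields, category, expected_eur", [
        ({"emergency_service_contacts": 2}, "emergency_services", "26.74"),
        ({"depot_injections": 1}, "depot_injections", "515.97"),
        ({"hospital_days": 4, "hospitalizations": 1}, "hospital_days", "950.00"),
        ({"sick_leave_days": 10}, "productivity_loss", "900.00"),
        ({"ebm_outpatient_eur": 314.37}, "ebm_services", "314.37"),
    ])
    def test_priced_and_passthrough_categories(self, unit_costs, fields,
                                               category, expected_eur):
        cost = compute_patient_phase_cost(make_patient(**fields), "a", unit_costs)
        assert cost.category_eur(category) == Decimal(expected_eur)
        assert cost.total_cents == cost.values[category]

    def test_sickness_benefit_rule_prices_days_beyond_42_only(self, unit_costs):
        patient = make_patient(sick_leave_days=50)
        all_days = compute_patient_phase_cost(patient, "a", unit_costs)
        benefit = compute_patient_phase_cost(patient, "a", unit_costs,
                                             productivity_rule="sickness_benefit")
        assert all_days.category_eur("productivity_loss") == Decimal("4500.00")
        assert benefit.category_eur("productivity_loss") == Decimal("720.00")

    def test_unknown_productivity_rule_is_rejected(self, unit_costs):
        with pytest.raises(ValueError, match="productivity_rule"):
            compute_patient_phase_cost(make_patient(), "a", unit_costs,
                                       productivity_rule="nonsense")

    def test_linearity_doubling_quantities_doubles_priced_categories(self, unit_costs):
        base_fields = dict(hospital_days=3, hospitalizations=1,
                           emergency_service_contacts=2, depot_injections=1,
                           sick_leave_days=8, day_clinic_days=5)
        single = compute_patient_phase_cost(make_patient(**base_fields), "a", unit_costs)
        doubled = compute_patient_phase_cost(
            make_patient(**{k: 2 * v for k, v in base_fields.items()}), "a", unit_costs)
        for cat in CATEGORIES:
            assert doubled.values[cat] == 2 * single.values[cat]


class TestAggregation:
    def test_single_patient_single_category(self, unit_costs):
        breakdowns = {"oral": [compute_patient_phase_cost(
            make_patient(ebm_outpatient_eur=100.0), "a", unit_costs)],
            "depot": [compute_patient_phase_cost(make_patient(), "b", unit_costs)]}
        table, totals = aggregate_costs(breakdowns)
        assert table.per_case_eur("oral", "ebm_services") == Decimal("100.00")
        assert totals["oral"].category_eur("ebm_services") == Decimal("100.00")

    def test_three_patients_match_hand_computed_sums(self, unit_costs):
        days = [2, 5, 0]
        patients = [make_patient(patient_id=f"P{i}", hospital_days=d,
                                 hospitalizations=1 if d else 0,
                                 medication_eur=100.0 * i)
                    for i, d in enumerate(days)]
        oral = [compute_patient_phase_cost(p, "a", unit_costs) for p in patients]
        depot = [compute_patient_phase_cost(p, "b", unit_costs) for p in patients]
        table, totals = aggregate_costs({"oral": oral, "depot": depot})
        # 7 hospital days x 237.50 €, medication 0+100+200 €
        assert totals["oral"].category_eur("hospital_days") == Decimal("1662.50")
        assert totals["oral"].category_eur("medication") == Decimal("300.00")
        assert table.per_case_cents["oral"]["medication"] == Fraction(30000, 3)

    def test_per_case_times_n_equals_sample_total(self, component_table):
        for arm in ("oral", "depot"):
            for cat in CATEGORIES:
                per_case = component_table.per_case_category_cents(arm, cat)
                assert per_case * component_table.n == \
                    component_table.sample_total_cents(arm, cat)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no breakdowns"):
            aggregate_costs({"oral": [], "depot": []})

    @given(st.lists(st.lists(st.integers(min_value=0, max_value=10**7),
                             min_size=13, max_size=13), min_size=1, max_size=8))
    def test_aggregation_conserves_totals_and_nonnegativity(self, rows):
        breakdowns = [CostBreakdown(dict(zip(CATEGORIES, row))) for row in rows]
        table, totals = aggregate_costs({"oral": breakdowns, "depot": breakdowns})
        total = totals["oral"]
        # conservation: total row equals the sum of category rows, cents-exact
        assert total.total_cents == sum(total.values.values())
        assert total.total_cents == sum(b.total_cents for b in breakdowns)
        assert all(v >= 0 for v in total.values.values())
        # scale consistency survives the exact division
        assert table.per_case_total_cents("oral") * len(rows) == total.total_cents


class TestComponentTable:
    def test_packaged_totals_match_published_per_case(self, component_table):
        assert component_table.per_case_total_eur("oral") == Decimal("9935.38")
        assert component_table.per_case_total_eur("depot") == Decimal("4557.56")

    def test_missing_category_is_named(self, component_table):
        data = component_table.to_dict()
        del data["arms"]["oral"]["hospital_days"]
        with pytest.raises(ValueError, match="hospital_days"):
            load_component_table(data)

    def test_extra_category_is_named(self, component_table):
        data = component_table.to_dict()
        data["arms"]["depot"]["unicorn_care"] = "1.00"
        with pytest.raises(ValueError, match="unicorn_care"):
            load_component_table(data)

    def test_write_read_round_trip_is_exact(self, component_table, tmp_path):
        path = tmp_path / "table.json"
        write_component_table(component_table, path)
        again = load_component_table(path)
        assert again.per_case_cents == component_table.per_case_cents
        assert again.n == component_table.n

    def test_per_case_scope_loading(self):
        arms = {arm: {c: "1.00" for c in CATEGORIES} for arm in ("oral", "depot")}
        table = load_component_table({"n": 10, "scope": "per_case", "arms": arms})
        assert table.per_case_total_eur("oral") == Decimal("13.00")
        assert table.sample_total_eur("oral") == Decimal("130.00")


class TestDerivedQuantities:
    def test_direct_indirect_split_identity(self):
        values = dict.fromkeys(CATEGORIES, 0)
        values["productivity_loss"] = 43702
        values["hospital_days"] = 565279
        direct, indirect, total = split_direct_indirect(CostBreakdown(values))
        assert indirect == Decimal("437.02")
        assert direct + indirect == total

    def test_zero_breakdown_splits_to_zero(self):
        assert split_direct_indirect(zero_breakdown()) == (0, 0, 0)

    def test_published_direct_costs(self, component_table):
        assert split_direct_indirect_per_case(component_table, "oral")[0] == \
            Decimal("9498.36")
        assert split_direct_indirect_per_case(component_table, "depot")[0] == \
            Decimal("4449.83")

    def test_oral_aripiprazole_share_of_medication(self, component_table):
        share = medication_share(component_table, "oral", 1562.49)
        assert share == pytest.approx(0.6383, abs=5e-4)
        # the residual equals the published medication cost net of the drug
        residual = component_table.per_case_category_cents("oral", "medication") \
            - to_cents("1562.49")
        assert abs(residual / 100 - Fraction("885.31")) < Fraction(1, 100)

    def test_medication_share_edge_cases(self, component_table):
        assert medication_share(component_table, "oral", 0) == 0.0
        with pytest.raises(ValueError, match="exceeds"):
            medication_share(component_table, "oral", 10**9)
        zero_table = load_component_table({
            "n": 1, "scope": "per_case",
            "arms": {arm: {c: 0 for c in CATEGORIES} for arm in ("oral", "depot")}})
        with pytest.raises(ValueError, match="zero"):
            medication_share(zero_table, "oral", 5.0)


class TestMoneyFormatting:
    def test_german_locale_swaps_separators_only(self):
        value = Decimal("260704250.62")
        assert fmt_eur(value, "en") == "260,704,250.62 €"
        assert fmt_eur(value, "de") == "260.704.250,62 €"

    @given(st.integers(min_value=0, max_value=10**13))
    def test_format_parse_round_trip(self, cents):
        value = Decimal(cents).scaleb(-2)
        for locale in ("en", "de"):
            assert parse_eur(fmt_eur(value, locale), locale) == value

    def test_unit_cost_range_validation(self):
        with pytest.raises(ValueError, match="hospital_day"):
            UnitCostTable(hospital_day_eur=500.0)
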