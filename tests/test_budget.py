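"""Budget engine: scenario pricing, offsets, aggregation and its invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmbia.budget import (
    BudgetImpactRow,
    aggregate,
    calibrate_atelectasis_cost,
    effective_events,
    evaluate,
    expected_events,
    per_procedure_offset,
    scenario_drug_cost,
    stratum_budget_impact,
)
from nmbia.cohort import BlockDepth, PriorAgent, PriorStrategy, Stratum
from nmbia.parameters import ParameterError, round_currency
from nmbia.synthetic import GeneratorConfig, generate_parameter_set


def _stratum(depth="moderate", strategy="no_reversal", agent="rocuronium_native"):
    return Stratum(BlockDepth(depth), PriorStrategy(strategy), PriorAgent(agent))


class TestScenarioDrugCost:
    @pytest.mark.parametrize("depth,strategy,scenario,expected", [
        ("moderate", "no_reversal", "prior", 1.80),
        ("moderate", "no_reversal", "alternative", 53.14),
        ("moderate", "neostigmine", "prior", 2.26),
        ("moderate", "neostigmine", "alternative", 53.14),
        ("deep", "no_reversal", "prior", 1.80),
        ("deep", "no_reversal", "alternative", 104.48),
    ])
    def test_base_case_prices(self, base_params, depth, strategy, scenario, expected):
        cost = scenario_drug_cost(_stratum(depth, strategy), scenario,
                                  base_params.drugs)
        assert round_currency(cost) == expected

    def test_switched_cells_priced_as_rocuronium_by_default(self, base_params):
        switched = _stratum(agent="cisatracurium_switched")
        native = _stratum()
        for scenario in ("prior", "alternative"):
            assert scenario_drug_cost(switched, scenario, base_params.drugs) == \
                scenario_drug_cost(native, scenario, base_params.drugs)

    def test_distinct_cisatracurium_price_applies_to_prior_only(self, base_params):
        drugs = base_params.drugs.model_copy(update={"cisatracurium": 3.50})
        switched = _stratum(agent="cisatracurium_switched")
        assert scenario_drug_cost(switched, "prior", drugs) == 3.50
        assert scenario_drug_cost(switched, "alternative", drugs) == \
            pytest.approx(1.80 + 51.34)


class TestOffset:
    def test_components_reproduce_hand_arithmetic(self, base_params):
        # (0.073-0.011) x 4999.40 + (0.040-0.019) x 4449.72
        events = base_params.events.model_copy(
            update={"offset_mode": "from_components"})
        assert round_currency(per_procedure_offset(events)) == 403.41

    def test_calibrated_mode_returns_calibrated_value(self, base_params):
        assert per_procedure_offset(base_params.events) == 307.61

    def test_equal_risks_give_zero_offset(self, base_params):
        events = base_params.events
        updates = {name: ev.model_copy(update={"risk_sugammadex": ev.risk_no_sugammadex})
                   for name, ev in events.types.items()}
        updates["offset_mode"] = "from_components"
        assert per_procedure_offset(events.model_copy(update=updates)) == pytest.approx(0.0)


class TestCalibration:
    def test_implied_atelectasis_cost_for_published_offset(self, base_params):
        # (307.61 - 0.021 x 4449.72) / 0.062
        cost = calibrate_atelectasis_cost(307.61, base_params.events)
        assert round_currency(cost) == 3454.29

    def test_calibration_inverts_the_component_sum(self, base_params):
        cost = calibrate_atelectasis_cost(403.40692, base_params.events)
        assert cost == pytest.approx(4999.40)

    def test_pneumonia_component_alone_implies_zero(self, base_params):
        ev = base_params.events
        target = ev.pneumonia.risk_difference * ev.pneumonia.unit_cost
        assert calibrate_atelectasis_cost(target, ev) == pytest.approx(0.0)

    def test_zero_risk_difference_rejected(self, base_params):
        ev = base_params.events
        flat = ev.model_copy(update={"atelectasis": ev.atelectasis.model_copy(
            update={"risk_sugammadex": ev.atelectasis.risk_no_sugammadex})})
        with pytest.raises(ParameterError):
            calibrate_atelectasis_cost(307.61, flat)

    def test_effective_events_reproduce_calibrated_offset(self, base_params):
        eff = effective_events(base_params.events)
        assert eff.offset_mode == "from_components"
        assert per_procedure_offset(eff) == pytest.approx(307.61, abs=1e-6)


class TestExpectedEvents:
    @pytest.mark.parametrize("n,risk,expected", [
        (228863, 0.021, 4806),     # pneumonias avoided at the risk difference
        (1_000_000, 0.0, 0),
        (100, 0.04, 4),
    ])
    def test_expected_counts(self, n, risk, expected):
        from nmbia.parameters import round_count
        assert round_count(expected_events(n, risk)) == expected


class TestRows:
    @pytest.mark.parametrize("row_key,unit_net", [
        ("moderate/no_reversal", 256.27),
        ("moderate/neostigmine", 256.73),
        ("deep/no_reversal", 204.93),
    ])
    def test_base_case_per_procedure_net(self, base_params, base_strata,
                                         row_key, unit_net):
        row = stratum_budget_impact(base_strata, row_key, base_params.drugs,
                                    base_params.events)
        assert round_currency(row.unit_net) == pytest.approx(unit_net, abs=0.01)

    def test_row_identity_holds(self, base_params, base_strata):
        for key in ("moderate/no_reversal", "moderate/neostigmine", "deep/no_reversal"):
            row = stratum_budget_impact(base_strata, key, base_params.drugs,
                                        base_params.events)
            assert row.net_saving == pytest.approx(
                row.offsets - (row.alternative_drug_cost - row.prior_drug_cost))

    def test_zero_count_row_has_zero_national_values(self, base_params, base_strata):
        from dataclasses import replace
        zeroed = [replace(sc, sugammadex_count=0) for sc in base_strata]
        row = stratum_budget_impact(zeroed, "moderate/no_reversal",
                                    base_params.drugs, base_params.events)
        assert row.prior_drug_cost == row.alternative_drug_cost == 0
        assert row.offsets == row.net_saving == 0


class TestAggregate:
    def test_published_component_totals(self):
        """Aggregating the published national components recovers the
        published total net saving and per-procedure averages."""
        printed = [  # (prior, alternative, offsets) per reversal row
            ("moderate/no_reversal", 212903, 6272453, 36308198),
            ("moderate/neostigmine", 184369, 4321505, 25015106),
            ("deep/no_reversal", 53225, 3083001, 9077049),
        ]
        rows = [BudgetImpactRow(row_key=k, n_sugammadex=0, prior_drug_cost=p,
                                alternative_drug_cost=a, offsets=o)
                for k, p, a, o in printed]
        # overall totals as printed (their row sums differ by 1 EUR rounding)
        report = aggregate(rows, {"sugammadex_total": 228863,
                                  "all_procedures_total": 733876})
        net_from_totals = 70400354 - (13676960 - 450498)
        assert net_from_totals == 57173892
        assert report.total_net_saving == pytest.approx(net_from_totals, abs=2.0)
        assert round_currency(net_from_totals / 228863) == 249.82
        assert round_currency(13676960 / 228863) == 59.76

    def test_single_row_totals_equal_that_row(self, base_params, base_strata):
        row = stratum_budget_impact(base_strata, "deep/no_reversal",
                                    base_params.drugs, base_params.events)
        report = aggregate([row], {"sugammadex_total": row.n_sugammadex,
                                   "all_procedures_total": 733876})
        assert report.total_net_saving == pytest.approx(row.net_saving)
        assert report.total_offsets == pytest.approx(row.offsets)

    def test_zero_denominator_rejected(self, base_params, base_strata):
        row = stratum_budget_impact(base_strata, "deep/no_reversal",
                                    base_params.drugs, base_params.events)
        with pytest.raises(ParameterError):
            aggregate([row], {"sugammadex_total": 0, "all_procedures_total": 733876})

    def test_empty_rows_rejected(self):
        with pytest.raises(ParameterError):
            aggregate([], {"sugammadex_total": 1, "all_procedures_total": 1})


class TestInvariants:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_identity_and_event_conservation(self, seed):
        """net = offsets - (alt - prior) and avoided = prior - alternative
        expected events, for every row and in total, on random inputs."""
        params = generate_parameter_set(GeneratorConfig(seed=seed))
        report = evaluate(params)
        for row in report.rows:
            assert row.net_saving == pytest.approx(
                row.offsets - (row.alternative_drug_cost - row.prior_drug_cost))
        assert report.total_net_saving == pytest.approx(
            report.total_offsets - (report.total_alternative_drug_cost
                                    - report.total_prior_drug_cost))
        for t, avoided in report.events_avoided.items():
            assert avoided == pytest.approx(
                report.events_prior[t] - report.events_alternative[t])

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 3.0))
    def test_offset_linear_in_unit_costs(self, seed, scale):
        params = generate_parameter_set(GeneratorConfig(seed=seed))
        events = params.events
        scaled = events.model_copy(update={
            name: ev.model_copy(update={"unit_cost": ev.unit_cost * scale})
            for name, ev in events.types.items()})
        assert per_procedure_offset(scaled) == pytest.approx(
            scale * per_procedure_offset(events))

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), extra=st.floats(1.0, 200.0))
    def test_net_monotone_in_sugammadex_price_and_event_costs(self, seed, extra):
        params = generate_parameter_set(GeneratorConfig(seed=seed))
        base_net = evaluate(params).total_net_saving
        pricier = params.model_copy(update={"drugs": params.drugs.model_copy(update={
            "sugammadex_moderate": params.drugs.sugammadex_moderate + extra,
            "sugammadex_deep": params.drugs.sugammadex_deep + 2 * extra})})
        assert evaluate(pricier).total_net_saving <= base_net
        events = params.events
        costlier_events = params.model_copy(update={"events": events.model_copy(update={
            name: ev.model_copy(update={"unit_cost": ev.unit_cost + extra})
            for name, ev in events.types.items()})})
        assert evaluate(costlier_events).total_net_saving >= base_net
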