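"""Costing layer: drug schedules, resource and complication costs, scenarios."""

import numpy as np
import pytest

from prucea import load_config
from prucea.costing import (
    build_cost_profiles,
    complication_cost_per_cycle,
    drug_cost_per_cycle,
    indirect_cost_per_cycle,
    resource_cost_per_cycle,
    transport_cost_per_cycle,
)
from prucea.engine import HealthState

S = HealthState


@pytest.fixture(scope="module")
def nominal():
    """Bundle with inflation switched off: costs stay at their list prices."""
    return load_config(
        overrides={
            "costs.inflation": {2009: 0.0, 2010: 0.0, 2011: 0.0, 2012: 0.0, 2013: 0.0}
        }
    )


class TestDrugCosts:
    def test_first_cycle_priced_on_starter_pack(self, nominal):
        cost = drug_cost_per_cycle("prucalopride", S.START_W1_4, 0, nominal)
        assert cost == pytest.approx(2.77 * 28 + 6.35)

    def test_later_start_cycles_use_post_pack_rate(self, nominal):
        cost = drug_cost_per_cycle("prucalopride", S.START_W5_8, 1, nominal)
        assert cost == pytest.approx(2.49 * (365 / 12) + 6.35, rel=1e-6)

    def test_year1_maintenance_spreads_130_treatment_days(self, nominal):
        per_cycle = drug_cost_per_cycle("prucalopride", S.MAINTENANCE, 5, nominal)
        annual = 130 * 2.49 + 130 / 28 * 6.35
        assert per_cycle * 9 == pytest.approx(annual, rel=1e-9)

    def test_later_years_use_220_day_cap(self, nominal):
        per_cycle = drug_cost_per_cycle("prucalopride", S.MAINTENANCE, 14, nominal)
        annual = 220 * 2.49 + 220 / 28 * 6.35
        assert per_cycle * 12 == pytest.approx(annual, rel=1e-9)
        # the cap bounds any maintenance year's prucalopride spend
        assert per_cycle * 12 <= 220 * 2.49 + 220 / 28 * 6.35 + 1e-9

    def test_laxative_arm_priced_on_weighted_basket(self, nominal):
        cost = drug_cost_per_cycle("laxative", S.MAINTENANCE, 5, nominal)
        assert cost == pytest.approx(0.4538 * (365 / 12) + 6.35, rel=1e-4)

    def test_prucalopride_arm_switch_states_carry_laxative_costs(self, nominal):
        for state in (S.SWITCH_W1_4, S.SWITCH_MAINTENANCE, S.DROPOUT):
            pru = drug_cost_per_cycle("prucalopride", state, 5, nominal)
            lax = drug_cost_per_cycle("laxative", state, 5, nominal)
            assert pru == lax

    def test_half_dose_scenario_prices_day_at_mean_rate(self, nominal):
        low = nominal.copy_deep()
        low.analysis.dose = "1.5mg"
        cost = drug_cost_per_cycle("prucalopride", S.START_W1_4, 0, low)
        assert cost == pytest.approx((2.77 + 1.95) / 2 * 28 + 6.35)

    def test_unknown_arm_rejected(self, nominal):
        with pytest.raises(ValueError):
            drug_cost_per_cycle("aspirin", S.START_W1_4, 0, nominal)


class TestResourceCosts:
    def test_start_phase_hand_sum(self, nominal):
        """Weeks 1-4 column x unit costs (DBC tariff for the specialist),
        plus the two configured procedure prices."""
        expected = (
            0.6 * 195.89   # specialist via DBC episode
            + 0.3 * 14.0   # specialist telephone at PCP telephone tariff
            + 0.9 * 28.0
            + 0.6 * 14.0
            + 0.2 * 10.0
            + 0.1 * 27.0
            + 0.2 * 62.0   # anoscopy/proctoscopy
            + 0.8 * 36.9   # blood tests
        )
        assert resource_cost_per_cycle(S.START_W1_4, nominal) == pytest.approx(expected)

    def test_responder_states_billed_at_manual_tariff(self, nominal):
        expected = (
            0.3 * 72.0 + 0.1 * 14.0 + 0.6 * 28.0 + 0.3 * 14.0
            + 0.1 * 10.0 + 0.1 * 27.0
            + 0.2 * 0.0 + 0.3 * 0.0 + 0.2 * 62.0 + 0.1 * 0.0
        )
        assert resource_cost_per_cycle(S.MAINTENANCE, nominal) == pytest.approx(expected)

    def test_doubling_unit_costs_doubles_the_result(self, nominal):
        doubled = nominal.copy_deep()
        for item in doubled.costs.units.values():
            item.cost *= 2
        for name in doubled.costs.procedure_prices:
            doubled.costs.procedure_prices[name] *= 2
        for state in S:
            assert resource_cost_per_cycle(state, doubled) == pytest.approx(
                2 * resource_cost_per_cycle(state, nominal)
            )

    def test_zero_profile_costs_nothing(self, nominal):
        zeroed = nominal.copy_deep()
        for table in (zeroed.resources.consultations, zeroed.resources.procedures):
            for row in table.values():
                for phase in row:
                    row[phase] = 0.0
        assert resource_cost_per_cycle(S.START_W1_4, zeroed) == 0.0


class TestComplicationCosts:
    def test_hemorrhoids_only_hand_sum(self, nominal):
        only = nominal.copy_deep()
        for name, rates in only.clinical.complications.items():
            if name != "hemorrhoids":
                rates.weeks_1_4 = 0.0
                rates.weeks_5_12 = 0.0
                rates.switch = 0.0
        cost = complication_cost_per_cycle(S.START_W1_4, only)
        bundle = 2.2 * 28.0 + 1.5 * 195.89 + 0.017 * 3102.0
        assert cost == pytest.approx(0.19 * bundle)

    def test_switch_probability_converted_from_eight_week_period(self, nominal):
        only = nominal.copy_deep()
        for name, rates in only.clinical.complications.items():
            if name != "hemorrhoids":
                rates.weeks_1_4 = rates.weeks_5_12 = rates.switch = 0.0
        cost = complication_cost_per_cycle(S.SWITCH_W1_4, only)
        monthly = 1.0 - (1.0 - 0.12) ** 0.5
        bundle = 2.2 * 28.0 + 1.5 * 195.89 + 0.017 * 3102.0
        assert cost == pytest.approx(monthly * bundle)

    def test_scenario_flag_removes_all_complication_costs(self, nominal):
        off = nominal.copy_deep()
        off.analysis.include_complications = False
        for state in S:
            assert complication_cost_per_cycle(state, off) == 0.0

    def test_small_probability_limit_is_linear(self, nominal):
        scaled = nominal.copy_deep()
        eps = 1e-4
        for rates in scaled.clinical.complications.values():
            rates.weeks_1_4 *= eps
        base = complication_cost_per_cycle(S.START_W1_4, nominal)
        assert complication_cost_per_cycle(S.START_W1_4, scaled) == pytest.approx(
            eps * base, rel=1e-3
        )

    def test_responder_states_accrue_no_complications(self, nominal):
        assert complication_cost_per_cycle(S.MAINTENANCE, nominal) == 0.0
        assert complication_cost_per_cycle(S.SWITCH_MAINTENANCE, nominal) == 0.0

    def test_los_scenario_is_cost_neutral_at_baseline_weights(self, nominal):
        """The LOS-based hospital cost uses daily cost = DBC tariff divided by
        the incidence-weighted mean stay, so the weighted mean stay re-prices
        to the DBC tariff."""
        los = nominal.copy_deep()
        los.analysis.hospital_costing = "los_daily"
        from prucea.costing import hospitalization_cost

        mgmt = nominal.resources.complication_management
        probs = nominal.clinical.complications
        weights = {
            n: probs[n].weeks_1_4 * m.hospitalization_fraction
            for n, m in mgmt.items()
        }
        total_w = sum(weights.values())
        mean_cost = (
            sum(weights[n] * hospitalization_cost(los, n) for n in mgmt) / total_w
        )
        assert mean_cost == pytest.approx(3102.0, rel=1e-9)


class TestTransportCosts:
    def test_maintenance_round_trips(self, nominal):
        expected = (
            0.3 * 2 * 7.0 * 0.20    # specialist
            + 0.6 * 2 * 1.1 * 0.20  # PCP
            + 0.1 * 2 * 1.1 * 0.20  # nurse at the PCP practice
            + 0.1 * 2 * 1.7 * 0.20  # dietician
        )
        assert transport_cost_per_cycle(S.MAINTENANCE, nominal) == pytest.approx(
            expected
        )

    def test_telephone_contacts_incur_no_transport(self, nominal):
        phone_only = nominal.copy_deep()
        for item in ("specialist", "pcp", "nurse", "dietician"):
            row = phone_only.resources.consultations[item]
            for phase in row:
                row[phase] = 0.0
        for state in S:
            assert transport_cost_per_cycle(state, phone_only) == 0.0

    def test_exclusion_scenario_zeroes_transport(self, nominal):
        off = nominal.copy_deep()
        off.analysis.include_transport = False
        assert transport_cost_per_cycle(S.MAINTENANCE, off) == 0.0

    def test_parking_scenario_adds_fee_per_visit(self, nominal):
        parking = nominal.copy_deep()
        parking.analysis.include_parking = True
        visits = 0.3 + 0.6 + 0.1 + 0.1  # face-to-face contacts, maintenance
        diff = transport_cost_per_cycle(S.MAINTENANCE, parking) - \
            transport_cost_per_cycle(S.MAINTENANCE, nominal)
        assert diff == pytest.approx(visits * 3.0)


class TestIndirectCosts:
    def test_off_by_default(self, nominal):
        assert indirect_cost_per_cycle(S.START_W1_4, nominal) == 0.0

    def test_monthly_productivity_loss_product(self, nominal):
        on = nominal.copy_deep()
        on.analysis.include_indirect = True
        expected = 0.870 * 0.12 * 2.4 * 8.0 * 26.99
        assert indirect_cost_per_cycle(S.START_W1_4, on) == pytest.approx(expected)

    def test_responders_lose_no_productivity(self, nominal):
        on = nominal.copy_deep()
        on.analysis.include_indirect = True
        assert indirect_cost_per_cycle(S.MAINTENANCE, on) == 0.0
        assert indirect_cost_per_cycle(S.SWITCH_MAINTENANCE, on) == 0.0


class TestProfiles:
    def test_zeroed_unit_costs_zero_all_nondrug_components(self, nominal):
        zeroed = nominal.copy_deep()
        for item in zeroed.costs.units.values():
            item.cost = 0.0
        for name in zeroed.costs.procedure_prices:
            zeroed.costs.procedure_prices[name] = 0.0
        zeroed.costs.transport.cost_per_km = 0.0
        profiles = build_cost_profiles(zeroed, 12)
        for profile in profiles.values():
            assert np.all(profile.medical == 0.0)
            assert np.all(profile.complication == 0.0)
            assert np.all(profile.transport == 0.0)

    def test_switching_flags_off_only_removes_cost(self, nominal):
        base = build_cost_profiles(nominal, 12)
        for flag in ("include_complications", "include_transport"):
            off = nominal.copy_deep()
            setattr(off.analysis, flag, False)
            reduced = build_cost_profiles(off, 12)
            for arm in base:
                assert np.all(reduced[arm].total() <= base[arm].total() + 1e-12)

    def test_components_are_nonnegative(self, params):
        profiles = build_cost_profiles(params, 12)
        for profile in profiles.values():
            for name in ("drug", "medical", "complication", "transport", "indirect"):
                assert np.all(profile.component(name) >= 0.0)
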