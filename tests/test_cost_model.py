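"""Dosing rules and itemized arm costs."""

import numpy as np
import pytest

from psmcea.cost_model import (CostInputs, DoseKind, DoseRule, PatientProfile,
                               cycle_drug_cost, dose_mg, total_discounted_cost)
from psmcea.model import evaluate_detailed
from psmcea.parameters import perturbed
from psmcea.psm_engine import build_trace


@pytest.fixture
def profile():
    return PatientProfile()  # BSA 1.64 m2, 60 kg, CrCl 70 mL/min


class TestDosing:
    @pytest.mark.parametrize("kind,amount,expected", [
        (DoseKind.FLAT_MG, 1200.0, 1200.0),
        (DoseKind.PER_KG, 15.0, 900.0),       # bevacizumab, 60 kg
        (DoseKind.PER_M2, 175.0, 287.0),      # paclitaxel, BSA 1.64
        (DoseKind.PER_M2, 50.0, 82.0),        # cisplatin
        (DoseKind.CALVERT_AUC, 5.0, 475.0),   # carboplatin: 5 * (70 + 25)
    ])
    def test_dose_rules(self, profile, kind, amount, expected):
        assert dose_mg(DoseRule(kind, amount), profile) == pytest.approx(expected)

    def test_nonpositive_amount_rejected(self):
        with pytest.raises(ValueError, match="amount"):
            DoseRule(DoseKind.FLAT_MG, 0.0)


class TestCycleDrugCost:
    def test_atezolizumab_administration_cost(self, base_inputs, profile):
        # flat 1200 mg at 3.88 USD/mg
        cost = cycle_drug_cost(base_inputs.intervention, profile,
                               base_inputs.config, 0, base_inputs.costs)
        ctrl = cycle_drug_cost(base_inputs.control, profile,
                               base_inputs.config, 0, base_inputs.costs)
        assert cost - ctrl == pytest.approx(1200 * 3.88)  # = 4656 USD

    def test_reduced_price_administration(self, base_inputs, profile):
        cheap = perturbed(base_inputs, "costs.price_atezolizumab", 1.47)
        cost = cycle_drug_cost(cheap.intervention, profile, cheap.config, 0,
                               cheap.costs)
        ctrl = cycle_drug_cost(cheap.control, profile, cheap.config, 0,
                               cheap.costs)
        assert cost - ctrl == pytest.approx(1764.0)  # 1200 mg at 1.47 USD/mg

    def test_platinum_mix_weighting(self, base_inputs, profile):
        # 50/50 cisplatin (82 mg x 0.22) / carboplatin (475 mg x 0.086)
        full = cycle_drug_cost(base_inputs.control, profile,
                               base_inputs.config, 0, base_inputs.costs)
        expected_platinum = 0.5 * 82 * 0.22 + 0.5 * 475 * 0.086
        bev, pac = 900 * 1.60, 287 * 0.24
        assert full == pytest.approx(bev + pac + expected_platinum)

    def test_induction_drugs_stop_after_six_cycles(self, base_inputs, profile):
        c5 = cycle_drug_cost(base_inputs.control, profile, base_inputs.config,
                             5, base_inputs.costs)
        c6 = cycle_drug_cost(base_inputs.control, profile, base_inputs.config,
                             6, base_inputs.costs)
        assert c6 < c5
        assert c6 == pytest.approx(900 * 1.60)  # bevacizumab maintenance only

    def test_maintenance_stops_at_response_cap(self, base_inputs, profile):
        cap = base_inputs.intervention.response_cap_months
        k_after = int(np.ceil(cap / base_inputs.config.cycle_length_months)) + 1
        cost = cycle_drug_cost(base_inputs.intervention, profile,
                               base_inputs.config, k_after, base_inputs.costs)
        assert cost == 0.0

    def test_cycle_outside_horizon_rejected(self, base_inputs, profile):
        with pytest.raises(ValueError, match="horizon"):
            cycle_drug_cost(base_inputs.control, profile, base_inputs.config,
                            500, base_inputs.costs)


class TestTotalCost:
    def test_items_sum_to_total(self, base_inputs):
        _, comp, ref = evaluate_detailed(base_inputs)
        for outcome in (comp, ref):
            d = outcome.costs.as_dict()
            parts = sum(v for k, v in d.items() if k != "total")
            assert parts == pytest.approx(d["total"], rel=1e-12)
            assert all(v >= 0 for v in d.values())

    def test_no_progressed_occupancy_means_no_downstream_cost(self, base_inputs):
        arm = base_inputs.intervention
        trace = build_trace(arm.pfs, arm.pfs, base_inputs.config, label=arm.name)
        breakdown = total_discounted_cost(arm, trace, base_inputs.costs,
                                          base_inputs.config, base_inputs.profile)
        assert breakdown.subsequent_therapy == 0.0
        assert breakdown.supportive_care == 0.0

    def test_total_cost_monotone_in_unit_price(self, base_inputs):
        base_total = evaluate_detailed(base_inputs)[1].costs.total
        for attr in ("price_atezolizumab", "sae_neutropenia",
                     "best_supportive_care", "follow_up"):
            bumped = perturbed(base_inputs, f"costs.{attr}",
                               getattr(base_inputs.costs, attr) * 1.5)
            assert evaluate_detailed(bumped)[1].costs.total >= base_total

    def test_currency_scale_invariance(self, base_inputs):
        res, comp, ref = evaluate_detailed(base_inputs)
        scaled = base_inputs.copy()
        scaled.costs = scaled.costs.scaled(7.05)  # e.g. USD -> RMB
        res2, comp2, ref2 = evaluate_detailed(scaled)
        assert comp2.costs.total == pytest.approx(7.05 * comp.costs.total, rel=1e-12)
        assert res2.incremental_cost == pytest.approx(
            7.05 * res.incremental_cost, rel=1e-12)
        assert res2.incremental_qaly == pytest.approx(res.incremental_qaly,
                                                      rel=1e-12)
        assert res2.icer == pytest.approx(7.05 * res.icer, rel=1e-12)

    def test_mismatched_trace_and_arm_rejected(self, base_inputs):
        trace = build_trace(base_inputs.control.pfs, base_inputs.control.os,
                            base_inputs.config, label="chemotherapy")
        with pytest.raises(ValueError, match="trace built for"):
            total_discounted_cost(base_inputs.intervention, trace,
                                  base_inputs.costs, base_inputs.config,
                                  base_inputs.profile)

    def test_sae_once_timing_charges_expected_cost_once(self, base_inputs):
        once = base_inputs.copy()
        once.config.sae_timing = "once"
        breakdown = evaluate_detailed(once)[1].costs
        arm, costs = once.intervention, once.costs
        expected = (0.15 * 531.70 + 0.18 * 461.50
                    + 0.05 * 88.38 + 0.18 * 12.90)
        assert breakdown.sae == pytest.approx(expected)
        assert arm.expected_sae_cost(costs) == pytest.approx(expected)

    def test_negative_cost_rejected(self, base_inputs):
        bad = perturbed(base_inputs, "costs.follow_up", -1.0)
        with pytest.raises(ValueError, match="follow_up"):
            evaluate_detailed(bad)
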