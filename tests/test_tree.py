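"""Decision-tree arithmetic, including the terminal-branch enumeration oracle."""

import copy

import numpy as np
import pytest

from vadcea.parameters import CvcExtras
from vadcea.tree import (FULL, dwell_years, evaluate_arm, evaluate_cvc,
                         evaluate_simple_arm, expected_complication_cost,
                         scenario_table, weighted_utility)


def enumerate_tree(params, arm_name, dwell=FULL):
    """Independent oracle: sum probability x payoff over terminal branches.

    Each arm terminates in one no-complication branch plus one branch per
    complication type (CVC 1+9, PICC 1+8, IVAP 1+7 = 27 paths in total);
    every branch carries the arm's fixed costs and its utility-weighted
    catheter time, and the typed branches add that type's management cost.
    """
    arm = params.arms[arm_name]
    p = arm.complications.probability
    if arm_name == "CVC":
        ex = params.cvc_extras
        fixed = ex.mean_insertions * (arm.insertion.mean + arm.maintenance.mean
                                      + arm.removal.mean)
        t = ex.mean_insertions * arm.survival.median
        base_qaly = ex.n_intermissions * ex.intermission_duration * ex.intermission_utility
    else:
        d = dwell_years(dwell, params)
        t = arm.survival.median if d == FULL else min(d, arm.survival.median)
        fixed = (arm.insertion.mean + (t / arm.maintenance_interval) * arm.maintenance.mean
                 + arm.removal.mean)
        base_qaly = 0.0
    cost = (1.0 - p) * fixed
    qaly = (1.0 - p) * (base_qaly + t * arm.utility.mean)
    n_paths = 1
    for ctype, share in arm.complications.mix.items():
        prob = p * share
        cost += prob * (fixed + arm.complications.type_costs[ctype].mean)
        qaly += prob * (base_qaly + t * arm.utility_with_complication.mean)
        n_paths += 1
    return cost, qaly, n_paths


class TestComponents:
    def test_weighted_utility_hand_values(self, params):
        assert weighted_utility(params.arms["PICC"]) == pytest.approx(0.879284, abs=1e-6)
        assert weighted_utility(params.arms["IVAP"]) == pytest.approx(0.944752, abs=1e-6)

    def test_weighted_utility_collapses_without_complications(self, params):
        arm = copy.deepcopy(params.arms["PICC"])
        arm.complications.probability = 0.0
        assert weighted_utility(arm) == arm.utility.mean

    def test_expected_complication_cost_brute_force(self, params):
        arm = params.arms["CVC"]
        by_hand = arm.complications.probability * sum(
            share * arm.complications.type_costs[t].mean
            for t, share in arm.complications.mix.items())
        assert expected_complication_cost(arm) == pytest.approx(by_hand, abs=1e-12)
        assert expected_complication_cost(arm) == pytest.approx(2.9918, abs=0.01)

    def test_single_type_half_probability(self, params):
        arm = copy.deepcopy(params.arms["IVAP"])
        arm.complications.probability = 0.5
        arm.complications.mix = {"occlusion": 1.0}
        arm.complications.type_costs["occlusion"].mean = 100.0
        assert expected_complication_cost(arm) == pytest.approx(50.0)

    def test_missing_type_cost_is_error(self, params):
        arm = copy.deepcopy(params.arms["IVAP"])
        arm.complications.mix["meteorite"] = 0.0
        with pytest.raises(KeyError, match="meteorite"):
            expected_complication_cost(arm)


class TestArmEvaluation:
    def test_picc_full_course(self, params):
        out = evaluate_simple_arm(params.arms["PICC"], FULL)
        assert out.expected_cost == pytest.approx(827.82, abs=0.05)
        assert out.expected_qaly == pytest.approx(0.36376, abs=1e-4)

    def test_dwell_shorter_than_median_scales_maintenance(self, params):
        out = evaluate_simple_arm(params.arms["IVAP"], 1.0)
        assert out.expected_cost == pytest.approx(1320.06, abs=0.05)
        assert out.expected_qaly == pytest.approx(0.944752, abs=1e-4)

    def test_zero_dwell_leaves_fixed_costs_only(self, params):
        arm = params.arms["IVAP"]
        out = evaluate_simple_arm(arm, 0.0)
        expected = (arm.insertion.mean + arm.removal.mean
                    + expected_complication_cost(arm))
        assert out.expected_cost == pytest.approx(expected, abs=1e-12)
        assert out.expected_qaly == 0.0

    def test_cvc_composite_outcome(self, params):
        out = evaluate_cvc(params.arms["CVC"], params.cvc_extras)
        assert out.expected_cost == pytest.approx(542.36, abs=0.05)
        assert out.expected_qaly == pytest.approx(0.24357, abs=1e-4)
        assert out.qaly_components["intermission"] > 0

    def test_single_insertion_has_no_intermission_qaly(self, params):
        ex = CvcExtras(mean_insertions=1.0, n_intermissions=1e-12,
                       intermission_duration=0.0686, intermission_utility=0.814)
        out = evaluate_cvc(params.arms["CVC"], ex)
        assert out.qaly_components["intermission"] == pytest.approx(0.0, abs=1e-10)

    def test_cvc_invariant_to_dwell(self, params):
        a = evaluate_arm(params, "CVC", "6m")
        b = evaluate_arm(params, "CVC", FULL)
        assert a.expected_cost == b.expected_cost
        assert a.expected_qaly == b.expected_qaly


class TestScenarios:
    def test_dwell_parsing(self, params):
        assert dwell_years("6m", params) == pytest.approx(180 / 365)
        assert dwell_years("12m", params) == 1.0
        assert dwell_years("1.5y", params) == 1.5
        assert dwell_years(FULL, params) == FULL
        with pytest.raises(ValueError):
            dwell_years("fortnight", params)

    def test_table_shape_and_dwell_invariance_above_median(self, params):
        outs = scenario_table(params, ("6m", "12m", FULL))
        assert len(outs) == 9
        for arm in ("CVC", "PICC"):  # medians below every scenario dwell
            costs = {o.expected_cost for o in outs if o.arm == arm}
            assert len(costs) == 1

    def test_empty_dwell_list_rejected(self, params):
        with pytest.raises(ValueError):
            scenario_table(params, ())

    def test_cost_monotone_and_qaly_saturates_in_dwell(self, params):
        arm = params.arms["IVAP"]
        dwells = [0.25, 0.5, 1.0, 2.0, 2.8493, 3.5, 10.0]
        outs = [evaluate_simple_arm(arm, d) for d in dwells]
        costs = [o.expected_cost for o in outs]
        qalys = [o.expected_qaly for o in outs]
        assert all(b >= a for a, b in zip(costs, costs[1:]))
        assert all(b > a for a, b in zip(qalys[:4], qalys[1:5]))
        assert qalys[-1] == qalys[-3]  # flat beyond the median

    def test_removing_complications_removes_exactly_that_component(self, params):
        p0 = copy.deepcopy(params)
        for arm in p0.arms.values():
            arm.complications.probability = 0.0
        for name in ("CVC", "PICC", "IVAP"):
            full = evaluate_arm(params, name)
            bare = evaluate_arm(p0, name)
            assert full.expected_cost - bare.expected_cost == pytest.approx(
                full.cost_components["complication"], abs=1e-9)
            assert bare.cost_components["complication"] == 0.0
            assert bare.expected_qaly >= full.expected_qaly


class TestTreeOracle:
    @pytest.mark.parametrize("dwell", ["6m", "12m", FULL])
    def test_expected_values_equal_branch_enumeration(self, params, dwell):
        total_paths = 0
        for arm in ("CVC", "PICC", "IVAP"):
            cost, qaly, n_paths = enumerate_tree(params, arm, dwell)
            out = evaluate_arm(params, arm, dwell)
            assert out.expected_cost == pytest.approx(cost, abs=1e-9)
            assert out.expected_qaly == pytest.approx(qaly, abs=1e-9)
            total_paths += n_paths
        assert total_paths == 27
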