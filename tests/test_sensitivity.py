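"""One-way tornado and probabilistic sensitivity analysis."""

import copy

import numpy as np
import pandas as pd
import pytest

from vadcea.cea import icer
from vadcea.parameters import DSA_KEYS
from vadcea.sensitivity import (_evaluate_draws, ceac, ceac_frame, one_way_dsa,
                                psa_scatter, sample_psa, tornado_frame)
from vadcea.tree import FULL, evaluate_arm


@pytest.fixture(scope="module")
def tornado(params):
    return one_way_dsa(params, ("IVAP", "CVC"))


class TestOneWayDsa:
    def test_covers_all_37_parameters_sorted_by_spread(self, tornado):
        assert len(tornado) == 37
        spreads = [e.spread for e in tornado]
        assert spreads == sorted(spreads, reverse=True)

    def test_maintenance_cost_dominates_tornado(self, tornado):
        assert tornado[0].key == "c3_IVAP_perMaintenance"

    def test_zero_width_interval_gives_zero_spread(self, params):
        p = copy.deepcopy(params)
        p.arms["IVAP"].removal.ci = (82.3272, 82.3272 + 1e-15)
        [entry] = one_way_dsa(p, ("IVAP", "CVC"), keys=["c3_IVAP_removal"])
        assert entry.spread == pytest.approx(0.0, abs=1e-6)

    def test_ten_percent_excursion_symmetric_for_linear_cost(self, params):
        p = copy.deepcopy(params)
        p.arms["IVAP"].removal.ci = None  # force the +/-10% rule
        base = icer(evaluate_arm(p, "IVAP"), evaluate_arm(p, "CVC")).icer
        [entry] = one_way_dsa(p, ("IVAP", "CVC"), keys=["c3_IVAP_removal"])
        assert entry.outcome_high - base == pytest.approx(base - entry.outcome_low,
                                                          rel=1e-9)

    def test_unknown_key_is_error(self, params):
        with pytest.raises(KeyError):
            one_way_dsa(params, keys=["c9_teleporter"])

    def test_base_case_consistency(self, params, results):
        base = icer(results.outcome("IVAP"), results.outcome("CVC")).icer
        [entry] = one_way_dsa(params, ("IVAP", "CVC"), keys=["u2_PICC"])
        # a parameter foreign to the pair leaves the ICER at base case
        assert entry.outcome_low == pytest.approx(base, rel=1e-12)
        assert entry.outcome_high == pytest.approx(base, rel=1e-12)

    def test_frame_export(self, tornado):
        df = tornado_frame(tornado)
        assert list(df.columns) == ["parameter", "low", "high",
                                    "outcome_low", "outcome_high", "spread"]
        assert len(df) == 37


@pytest.fixture(scope="module")
def draws(params):
    return sample_psa(params, n=4000, seed=42)


class TestPsa:
    def test_seed_reproducibility(self, params):
        a = sample_psa(params, n=50, seed=9)
        b = sample_psa(params, n=50, seed=9)
        pd.testing.assert_frame_equal(a.params, b.params)
        c = sample_psa(params, n=50, seed=10)
        assert not a.params.equals(c.params)

    def test_draws_respect_parameter_supports(self, draws):
        p = draws.params
        for key in DSA_KEYS:
            col = p[key]
            if key.startswith(("u", "p")):
                assert ((col >= 0) & (col <= 1)).all(), key
            else:
                assert (col >= 0).all(), key
        assert (p["CVC_mean_insertionTimes"] >= 1.0).all()

    def test_outcome_means_near_base_case(self, draws, results):
        for arm in ("CVC", "PICC", "IVAP"):
            base = results.outcome(arm)
            assert draws.outcomes[arm]["cost"].mean() == pytest.approx(
                base.expected_cost, rel=0.02)
            assert draws.outcomes[arm]["qaly"].mean() == pytest.approx(
                base.expected_qaly, rel=0.02)

    def test_vectorized_tree_matches_scalar_tree(self, params, draws):
        i = 17
        p_i = params
        for key in DSA_KEYS:
            p_i = p_i.with_value(key, float(draws.params[key].iloc[i]))
        for arm in ("CVC", "PICC", "IVAP"):
            out = evaluate_arm(p_i, arm, FULL)
            assert draws.outcomes[arm]["cost"].iloc[i] == pytest.approx(
                out.expected_cost, abs=1e-9)
            assert draws.outcomes[arm]["qaly"].iloc[i] == pytest.approx(
                out.expected_qaly, abs=1e-9)

    def test_degenerate_draws_reproduce_base_case(self, params, results):
        base_vals = {k: [params.get_value(k)] * 3 for k in DSA_KEYS}
        outcomes = _evaluate_draws(params, pd.DataFrame(base_vals))
        for arm in ("CVC", "PICC", "IVAP"):
            assert outcomes[arm]["cost"].iloc[0] == pytest.approx(
                results.outcome(arm).expected_cost, abs=1e-9)

    def test_infeasible_distribution_names_parameter(self, params):
        bad = copy.deepcopy(params)
        bad.arms["IVAP"].utility.sd = 0.5  # beta-infeasible spread
        bad.arms["IVAP"].utility.ci = None
        with pytest.raises(ValueError, match="u3_IVAP"):
            sample_psa(bad, n=5, seed=0)


class TestCeacAndScatter:
    def test_probabilities_partition_at_every_gridpoint(self, draws):
        pts = ceac(draws, np.linspace(0, 40000, 41))
        for p in pts:
            assert sum(p.probability.values()) == pytest.approx(1.0, abs=1e-9)

    def test_cvc_optimal_at_zero_wtp_and_crossing(self, draws):
        pts = ceac(draws, [0.0, 40000.0])
        assert pts[0].probability["CVC"] > 0.99
        assert pts[1].probability["IVAP"] > pts[1].probability["CVC"]
        # monotone crossing: IVAP overtakes CVC exactly once on a fine grid
        frame = ceac_frame(ceac(draws, np.linspace(0, 5000, 101)))
        sign = np.sign(frame["p_IVAP"] - frame["p_CVC"])
        flips = np.sum(np.diff(sign[sign != 0]) != 0)
        assert flips == 1

    def test_scatter_reference_excluded_and_signs_match_base(self, draws, results):
        clouds = psa_scatter(draws, "CVC")
        assert set(clouds) == {"PICC", "IVAP"}
        for arm, cloud in clouds.items():
            base_dc = (results.outcome(arm).expected_cost
                       - results.outcome("CVC").expected_cost)
            base_dq = (results.outcome(arm).expected_qaly
                       - results.outcome("CVC").expected_qaly)
            assert np.sign(cloud["delta_cost"].mean()) == np.sign(base_dc)
            assert np.sign(cloud["delta_qaly"].mean()) == np.sign(base_dq)
        # the IVAP cloud sits in the upper-right quadrant vs CVC
        ivap = clouds["IVAP"]
        assert ivap["delta_cost"].mean() > 0 and ivap["delta_qaly"].mean() > 0

    def test_empty_draws_rejected(self, params):
        d = sample_psa(params, n=1, seed=0)
        d.params = d.params.iloc[:0]
        with pytest.raises(ValueError):
            ceac(d)
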