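"""Parameter containers, config round-trips, and sampling distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vadcea.parameters import (DSA_KEYS, CostParam, SchemaError, SurvivalSpec,
                               UtilityParam, ValidationError,
                               default_parameters, derive_sampling_distribution,
                               dsa_bounds, gompertz_rate_from_median,
                               load_parameters, write_parameters)


class TestDefaults:
    @pytest.mark.parametrize("key,expected", [
        ("c3_IVAP_insertion", 844.8203),
        ("c2_PICC_perMaintenance", 21.6773),
        ("p2_PICC_complication", 0.0728),
        ("T3_IVAP_medianSurvivalTime", 2.8493),
        ("u1_CVC_intermission", 0.814),
        ("CVC_mean_insertionTimes", 4.5589),
    ])
    def test_base_case_values(self, params, key, expected):
        assert params.get_value(key) == pytest.approx(expected, abs=1e-12)

    def test_complication_counts_and_mixes(self, params):
        picc = params.arms["PICC"].complications
        assert picc.n_events == 55 and picc.n_patients == 756
        for arm in params.arms.values():
            assert sum(arm.complications.mix.values()) == pytest.approx(1.0, abs=1e-9)
            assert set(arm.complications.mix) <= set(arm.complications.type_costs)

    def test_cvc_cycle_consistency(self, params):
        ex = params.cvc_extras
        assert ex.n_intermissions == pytest.approx(ex.mean_insertions - 1, abs=1e-6)

    def test_all_dsa_keys_reachable_and_settable(self, params):
        assert len(DSA_KEYS) == 37
        for key in DSA_KEYS:
            v = params.get_value(key)
            assert np.isfinite(v)
            bumped = params.with_value(key, v * 0.5)
            assert bumped.get_value(key) == pytest.approx(v * 0.5)
            # the original object is untouched
            assert params.get_value(key) == pytest.approx(v)

    def test_shared_complication_cost_key_updates_every_arm(self, params):
        bumped = params.with_value("c_complication_thrombosis", 99.0)
        for arm in bumped.arms.values():
            assert arm.complications.type_costs["thrombosis"].mean == 99.0


class TestConfigIO:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_roundtrip_identity(self, params, tmp_path, suffix):
        path = tmp_path / f"params{suffix}"
        write_parameters(params, path)
        assert load_parameters(path) == params

    def test_missing_parameter_is_schema_error(self, params, tmp_path):
        import json
        path = tmp_path / "p.json"
        write_parameters(params, path)
        cfg = json.loads(path.read_text())
        del cfg["parameters"]["p2_PICC_complication"]
        path.write_text(json.dumps(cfg))
        with pytest.raises(SchemaError, match="p2_PICC_complication"):
            load_parameters(path)

    def test_out_of_range_utility_is_validation_error(self, params, tmp_path):
        import json
        path = tmp_path / "p.json"
        write_parameters(params, path)
        cfg = json.loads(path.read_text())
        cfg["parameters"]["u2_PICC"]["mean"] = 1.2
        path.write_text(json.dumps(cfg))
        with pytest.raises(ValidationError):
            load_parameters(path)

    def test_negative_cost_is_validation_error(self, params, tmp_path):
        import json
        path = tmp_path / "p.json"
        write_parameters(params, path)
        cfg = json.loads(path.read_text())
        cfg["parameters"]["c1_CVC_removal"]["mean"] = -3.0
        path.write_text(json.dumps(cfg))
        with pytest.raises(ValidationError):
            load_parameters(path)


class TestSamplingDistributions:
    def test_gamma_method_of_moments(self):
        d = derive_sampling_distribution(CostParam(68.0747, sd=43.2521), "gamma",
                                         sd=43.2521)
        assert d.params["shape"] == pytest.approx(2.477, abs=1e-3)
        assert d.params["rate"] == pytest.approx(0.03639, abs=1e-5)

    def test_per_maintenance_patient_sd_from_interval(self, params):
        cp = params.arms["PICC"].maintenance
        assert cp.patient_sd == pytest.approx((42.9217 - 0.433) / 3.92, abs=1e-9)
        # the interval is a patient-level range; the SE divides by sqrt(n)
        assert cp.se == pytest.approx(cp.patient_sd / math.sqrt(756), rel=1e-9)

    def test_zero_sd_gives_point_mass(self, rng):
        d = derive_sampling_distribution(UtilityParam(0.5, sd=0.0), "beta", sd=0.0)
        assert d.family == "point"
        assert np.all(d.rvs(rng, 5) == 0.5)

    def test_infeasible_beta_sd_raises(self):
        with pytest.raises(ValidationError, match="infeasible"):
            derive_sampling_distribution(UtilityParam(0.9), "beta", sd=0.5)

    def test_beta_from_complication_counts(self, params, rng):
        prof = params.arms["IVAP"].complications
        d = derive_sampling_distribution(prof, "beta")
        assert d.params == {"a": 58.0, "b": 1454.0}
        assert d.mean() == pytest.approx(58 / 1512, abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(mean=st.floats(5.0, 500.0), cv=st.floats(0.01, 0.8))
    def test_gamma_reproduces_target_moments(self, mean, cv):
        sd = cv * mean
        d = derive_sampling_distribution(CostParam(mean), "gamma", sd=sd)
        assert d.mean() == pytest.approx(mean, abs=1e-9)
        assert d.params["shape"] / d.params["rate"] ** 2 == pytest.approx(sd ** 2, rel=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(mean=st.floats(0.05, 0.95), frac=st.floats(0.05, 0.9))
    def test_beta_reproduces_target_mean(self, mean, frac):
        sd = frac * math.sqrt(mean * (1 - mean))  # always feasible
        d = derive_sampling_distribution(UtilityParam(mean), "beta", sd=sd)
        assert d.mean() == pytest.approx(mean, abs=1e-9)

    def test_mean_matched_lognormal_for_median_survival(self):
        spec = SurvivalSpec(median=0.01096, family="lognormal")
        d = derive_sampling_distribution(spec, "lognormal-median")
        assert d.mean() == pytest.approx(0.01096, abs=1e-9)

    def test_truncated_normal_preserves_mean(self, rng):
        d = derive_sampling_distribution(CostParam(4.5589, sd=1.0), "normal",
                                         sd=1.0, lower=1.0)
        assert d.family == "truncated-normal"
        assert d.mean() == pytest.approx(4.5589, abs=1e-9)
        draws = d.rvs(rng, 200_000)
        assert draws.min() >= 1.0
        assert draws.mean() == pytest.approx(4.5589, abs=0.01)

    def test_gompertz_median_sampling_centers_on_median(self, rng):
        spec = SurvivalSpec(median=0.4137, family="gompertz",
                            fitted_params={"shape": 2.0})
        d = derive_sampling_distribution(spec, "gompertz-median")
        draws = d.rvs(rng, 100_000)
        assert np.median(draws) == pytest.approx(0.4137, rel=0.01)

    def test_gompertz_rate_solves_median(self):
        b = gompertz_rate_from_median(0.7, 2.8493)
        med = math.log1p(0.7 * math.log(2) / b) / 0.7
        assert med == pytest.approx(2.8493, abs=1e-12)


class TestDsaBounds:
    def test_ci_bounds_used_when_printed(self, params):
        lo, hi = dsa_bounds(params, "c3_IVAP_perMaintenance")
        assert (lo, hi) == (0.6413, 63.6376)

    def test_ten_percent_rule_without_ci(self, params):
        lo, hi = dsa_bounds(params, "p3_IVAP_complication")
        assert lo == pytest.approx(0.9 * 0.0384)
        assert hi == pytest.approx(1.1 * 0.0384)

    def test_negative_printed_bound_clipped_to_support(self, params):
        lo, hi = dsa_bounds(params, "c_complication_infection")
        assert lo == 0.0 and hi == pytest.approx(312.4816)
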