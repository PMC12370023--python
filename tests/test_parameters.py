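"""Parameter containers, config loading, moment matching and PSA sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacscreen import load_parameters, moment_match, sample_parameter_set
from cacscreen.parameters import (
    DistributionSpec,
    ParameterError,
    ParameterSet,
    ValidationError,
)


class TestDistributionSpec:
    def test_beta_infeasible_se_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            DistributionSpec("beta", 0.5, 0.6)

    def test_gamma_requires_positive_mean(self):
        with pytest.raises(ValidationError):
            DistributionSpec("gamma", 0.0, 1.0)

    @pytest.mark.parametrize(
        "family,mean,se,expected",
        [
            # utility 0.828 (0.038): method-of-moments alpha/beta
            ("beta", 0.828, 0.038, (80.834, 16.792)),
            # CAC test 4,000 (400): shape = m^2/s^2, scale = s^2/m
            ("gamma", 4000.0, 400.0, (100.0, 40.0)),
        ],
    )
    def test_moment_match_examples(self, family, mean, se, expected):
        a, b = moment_match(DistributionSpec(family, mean, se))
        assert a == pytest.approx(expected[0], abs=5e-3)
        assert b == pytest.approx(expected[1], abs=5e-3)

    def test_fixed_is_point_mass(self):
        spec = DistributionSpec("fixed", 0.03, 0.5)
        rng = np.random.default_rng(0)
        assert {spec.rvs(rng) for _ in range(10)} == {0.03}

    @settings(max_examples=200, deadline=None)
    @given(
        family=st.sampled_from(["beta", "gamma", "lognormal"]),
        mean=st.floats(0.01, 0.99),
        rel_se=st.floats(0.01, 0.4),
    )
    def test_moment_match_round_trip(self, family, mean, rel_se):
        """The matched distribution's analytic mean and SD equal (mean, se)."""
        se = rel_se * mean
        if family == "beta" and se**2 >= mean * (1 - mean):
            return
        a, b = moment_match(DistributionSpec(family, mean, se))
        if family == "beta":
            m = a / (a + b)
            v = a * b / ((a + b) ** 2 * (a + b + 1))
        elif family == "gamma":
            m, v = a * b, a * b**2
        else:
            m = math.exp(a + b**2 / 2)
            v = (math.exp(b**2) - 1) * math.exp(2 * a + b**2)
        assert m == pytest.approx(mean, abs=1e-9)
        assert math.sqrt(v) == pytest.approx(se, abs=1e-9)


class TestLoading:
    def test_base_case_values(self, base_params):
        assert base_params.costs.statin_high_annual == 9071
        assert base_params.incidence["no_statin_overall"].mi == 0.00558
        assert base_params.wtp_threshold == 160000

    def test_cac_probs_normalized(self, base_params):
        probs = base_params.initial["cac_screening"].category_probs
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        # printed 0.36/0.39/0.26 sum to 1.01; each divided by 1.01
        assert probs["cac_ge100"] == pytest.approx(0.36 / 1.01, abs=1e-9)
        assert probs["cac_1_99"] == pytest.approx(0.39 / 1.01, abs=1e-9)
        assert probs["cac_0"] == pytest.approx(0.26 / 1.01, abs=1e-9)

    def test_missing_life_table_named_in_error(self, tmp_path, base_params):
        import yaml

        cfg_path = tmp_path / "broken.yaml"
        with open(load_parameters.__globals__["default_config_path"]()) as fh:
            cfg = yaml.safe_load(fh)
        del cfg["life_table"]
        cfg_path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ParameterError, match="life_table"):
            load_parameters(cfg_path)

    def test_serialization_round_trip_idempotent(self, base_params):
        d1 = base_params.to_dict()
        d2 = ParameterSet.from_dict(d1).to_dict()
        assert d1 == d2

    def test_unknown_path_rejected(self, base_params):
        with pytest.raises(ParameterError, match="no_such"):
            base_params.copy().set("costs.no_such_field", 1.0)


class TestSampling:
    def test_deterministic_under_seed(self, base_params):
        a = sample_parameter_set(base_params, 123)
        b = sample_parameter_set(base_params, 123)
        assert a.to_dict() == b.to_dict()
        c = sample_parameter_set(base_params, 124)
        assert c.to_dict() != a.to_dict()

    def test_rr_sample_mean_matches_table(self, base_params):
        """10,000 lognormal draws of the moderate-statin MI RR average 0.76."""
        spec = base_params.distributions["statin_effect.moderate.rr_mi"]
        assert spec.family == "lognormal" and spec.mean == 0.76
        rng = np.random.default_rng(5)
        draws = np.array([spec.rvs(rng) for _ in range(10_000)])
        assert abs(draws.mean() - 0.76) < 3 * 0.026 / math.sqrt(10_000)

    def test_sampled_sets_remain_valid_and_normalized(self, base_params):
        for seed in range(20):
            drawn = sample_parameter_set(base_params, seed)
            drawn.validate()  # must not raise
            for arm in ("current_practice", "cac_screening"):
                total = sum(drawn.initial[arm].category_probs.values())
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_fixed_family_constant_across_draws(self, base_params):
        p = base_params.copy()
        p.distributions = {
            "costs.cac_test": DistributionSpec("fixed", 4000.0, 0.0)
        }
        p.tornado_parameters = []
        values = {sample_parameter_set(p, s).costs.cac_test for s in range(5)}
        assert values == {4000.0}
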