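"""Tests for the synthetic open-population generator and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from prev2inc.core import SurvivalPair, estimate_wave_pair, incidence
from prev2inc.errors import ConfigurationError
from prev2inc.estimators import PrevalenceToIncidence
from prev2inc.simulate import (
    SimScenario,
    attrition_factor,
    default_standard_population,
    generate_surveys,
    mi_like_scenario,
    propagate_prevalence,
    survival_table_from_scenario,
)
from tests.conftest import stratum_weights


class TestPropagate:
    def test_no_incidence_proportional_attrition(self):
        assert propagate_prevalence(0.07, 0.0, 0.9, 0.9, 2.0, 50) == pytest.approx(0.07)

    def test_all_positives_die(self):
        assert propagate_prevalence(0.05, 0.0, 0.0, 0.9, 2.0, 50) == 0.0

    def test_prevalence_grows_with_hazard(self):
        ps = [
            propagate_prevalence(0.05, h, 0.85, 0.98, 2.0, 100)
            for h in (0.0, 0.01, 0.02, 0.05)
        ]
        assert all(a < b for a, b in zip(ps, ps[1:]))


class TestGenerateSurveys:
    def test_expected_mode_is_the_propagator(self, scenario):
        waves = generate_surveys(scenario)
        assert len(waves) == scenario.n_waves
        w0, w1 = waves[0], waves[1]
        for i in range(len(w0)):
            row = scenario.strata.iloc[i]
            expected = propagate_prevalence(
                row["p_init"], row["true_hazard"], row["SP_true"], row["SN_true"],
                scenario.T, scenario.m_substeps,
            )
            assert w1["p"].iloc[i] == pytest.approx(expected)
        assert w0["wave_start_year"].iloc[0] == 2000
        assert w1["wave_start_year"].iloc[0] == 2002

    def test_binomial_seed_reproducible(self):
        sc = mi_like_scenario(mode="binomial", n_per_stratum=500, seed=42)
        a = generate_surveys(sc)
        b = generate_surveys(sc)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_binomial_differs_across_seeds(self):
        a = generate_surveys(mi_like_scenario(mode="binomial", n_per_stratum=500, seed=1))
        b = generate_surveys(mi_like_scenario(mode="binomial", n_per_stratum=500, seed=2))
        assert not np.allclose(a[1]["p"], b[1]["p"])

    def test_binomial_converges_to_expected(self):
        exp = generate_surveys(mi_like_scenario(n_waves=2))
        big = generate_surveys(
            mi_like_scenario(n_waves=2, mode="binomial", n_per_stratum=1_000_000, seed=3)
        )
        assert np.abs(big[1]["p"] - exp[1]["p"]).max() < 1e-3

    def test_scenario_validation(self):
        strata = mi_like_scenario().strata
        with pytest.raises(ConfigurationError, match="n_waves"):
            SimScenario(strata=strata, n_waves=1)
        with pytest.raises(ConfigurationError, match="n_per_stratum"):
            SimScenario(strata=strata, mode="binomial")

    def test_yaml_round_trip(self, tmp_path):
        sc = mi_like_scenario(mode="binomial", n_per_stratum=250, seed=9)
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        back = SimScenario.from_yaml(path)
        pd.testing.assert_frame_equal(
            back.strata, sc.strata[back.strata.columns], check_dtype=False
        )
        assert (back.T, back.n_waves, back.mode, back.seed) == (2.0, 7, "binomial", 9)


class TestParameterRecovery:
    """End-to-end recovery of known truth from expected-value surveys.

    The estimator recovers the survivor-attrited hazard h*kappa(SP/SN)
    (see the oracle-equivalence tests); the standardized estimate is
    checked against the correspondingly attrited standardized truth, and
    against raw truth in a mild-differential-mortality scenario where the
    attrition factor is near 1.
    """

    def _standardized_estimate(self, scenario):
        waves = generate_surveys(scenario)
        model = PrevalenceToIncidence(
            survival=survival_table_from_scenario(scenario),
            standard_population=default_standard_population(scenario),
            ci_level=None,
        ).fit(pd.concat(waves, ignore_index=True))
        return model.standardized_["rate_per_100k"].iloc[0]

    def test_recovers_attrition_corrected_truth(self, scenario, scenario_standard):
        w = stratum_weights(scenario, scenario_standard)
        kappa = np.array(
            [
                attrition_factor(sp, sn)
                for sp, sn in zip(scenario.strata["SP_true"], scenario.strata["SN_true"])
            ]
        )
        truth = float(np.dot(w, scenario.strata["true_hazard"] * kappa)) * 1e5
        est = self._standardized_estimate(scenario)
        assert est == pytest.approx(truth, rel=0.04)

    def test_recovers_raw_truth_under_mild_mortality(self, scenario, scenario_standard):
        mild = scenario.with_(
            strata=scenario.strata.assign(
                SP_true=[0.97, 0.96, 0.96, 0.95, 0.95] * 2,
                SN_true=[0.995, 0.99, 0.985, 0.98, 0.975] * 2,
            ),
            n_waves=2,
        )
        w = stratum_weights(mild, scenario_standard)
        truth = float(np.dot(w, mild.strata["true_hazard"])) * 1e5
        est = self._standardized_estimate(mild)
        assert est == pytest.approx(truth, rel=0.05)

    def test_zero_hazard_null(self, scenario):
        null = scenario.with_(
            strata=scenario.strata.assign(true_hazard=0.0), n_waves=3
        )
        waves = generate_surveys(null)
        surv = survival_table_from_scenario(null)
        for w0, wT in zip(waves, waves[1:]):
            est = estimate_wave_pair(w0, wT, surv, ci_level=None)
            assert np.abs(est["rate"]).max() < 1e-12
        assert abs(self._standardized_estimate(null)) * 1e-5 < 1e-12

    def test_estimate_strictly_increases_with_hazard(self, scenario):
        values = []
        for scale in (0.5, 1.0, 2.0):
            sc = scenario.with_(
                strata=scenario.strata.assign(
                    true_hazard=scenario.strata["true_hazard"] * scale
                ),
                n_waves=2,
            )
            values.append(self._standardized_estimate(sc))
        assert values[0] < values[1] < values[2]


def test_attrition_factor_limits():
    assert attrition_factor(0.95, 0.95) == 1.0
    assert attrition_factor(0.81, 0.98) == pytest.approx(0.9105, abs=2e-4)
    # smaller relative survival of converts -> smaller factor
    assert attrition_factor(0.6, 0.98) < attrition_factor(0.9, 0.98) < 1.0
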