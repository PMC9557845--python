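"""Analytic estimands: population OLS, bias algebra, recommendations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from changesim import (
    CalibrationConstants,
    ChangesimError,
    CollinearityError,
    CovarianceStructure,
    DegenerateDifferenceError,
    bias_decomposition,
    build_scenario,
    estimands,
    oldham_correlation,
    population_ols,
    recommend_analysis,
)
from changesim.oracle import CHANGE_SCORE_WARNING, estimand_table


class TestPopulationOLS:
    def test_single_predictor_is_cov_over_var(self):
        cov = CovarianceStructure(("X", "Y"), [[4.0, 1.0], [1.0, 2.0]], [0.0, 0.0])
        coefs, intercept = population_ols(cov, "Y", ["X"])
        assert coefs["X"] == pytest.approx(0.25)
        assert intercept == 0.0

    def test_uncorrelated_predictors_keep_simple_coefficients(self):
        cov = CovarianceStructure(
            ("A", "B", "Y"),
            [[2.0, 0.0, 1.0], [0.0, 3.0, 1.5], [1.0, 1.5, 4.0]],
            [0.0, 0.0, 0.0],
        )
        coefs, _ = population_ols(cov, "Y", ["A", "B"])
        assert coefs["A"] == pytest.approx(0.5)
        assert coefs["B"] == pytest.approx(0.5)

    def test_intercept_from_means(self):
        cov = CovarianceStructure(("X", "Y"), [[1.0, 0.5], [0.5, 1.0]], [2.0, 3.0])
        coefs, intercept = population_ols(cov, "Y", ["X"])
        assert intercept == pytest.approx(3.0 - 0.5 * 2.0)

    def test_singular_predictors_rejected(self):
        cov = CovarianceStructure(
            ("A", "B", "Y"),
            [[1.0, 1.0, 0.3], [1.0, 1.0, 0.3], [0.3, 0.3, 1.0]],
            [0.0, 0.0, 0.0],
        )
        with pytest.raises(CollinearityError):
            population_ols(cov, "Y", ["A", "B"])

    def test_scenario_2a_adjusted_recovers_total_effect(self, scenario_2a):
        from changesim import implied_covariance

        cov = implied_covariance(scenario_2a.model)
        coefs, _ = population_ols(cov, "IC1", ["WC0", "IC0"])
        assert round(coefs["WC0"], 3) == 0.200


class TestEstimands:
    def test_scenario_1a_all_three_equal_total(self, scenario_1a):
        es = estimands(scenario_1a)
        for value in (es.alpha1, es.beta1, es.gamma1):
            assert round(value, 3) == 0.200

    def test_scenario_3a_sign_reversal(self, scenario_3a):
        es = estimands(scenario_3a)
        assert round(es.beta1, 3) == -0.031
        assert round(es.alpha1, 3) == 0.050
        assert round(es.gamma1, 3) == 0.200
        assert es.beta1 < 0 < es.direct_effect < es.total_effect

    def test_null_effect_independent_baseline_gives_zero_everywhere(self):
        k = CalibrationConstants(t_total_std=0.0)
        es = estimands(build_scenario("1A", k))
        assert es.alpha1 == pytest.approx(0.0, abs=1e-12)
        assert es.beta1 == pytest.approx(0.0, abs=1e-12)
        assert es.gamma1 == pytest.approx(0.0, abs=1e-12)

    def test_standardized_flag_rescales_by_sd_ratio(self, scenario_3a):
        nat, std = estimands(scenario_3a), estimands(scenario_3a, standardized=True)
        assert std.gamma1 == pytest.approx(nat.gamma1 * 2.165)
        assert std.total_effect == pytest.approx(0.433)

    @given(
        t=st.floats(min_value=-0.5, max_value=0.5),
        c=st.floats(min_value=-0.5, max_value=0.5),
        u2=st.floats(min_value=-0.4, max_value=0.4),
    )
    def test_randomization_limit_without_wc0_ic0_dependence(self, t, c, u2):
        # no edge (and no latent path) between WC0 and IC0: the three
        # estimands coincide, as for a randomized exposure
        k = CalibrationConstants(
            t_total_std=t,
            c_stab_std=c,
            u_loadings={"U2->IC0": u2, "U2->IC1": u2},
        )
        es = estimands(build_scenario("1A", k))
        assert abs(es.beta1 - es.alpha1) < 1e-9
        assert abs(es.alpha1 - es.gamma1) < 1e-9
        # 3A+ without mediation arc: U2 couples IC0 and IC1 but not WC0
        es2 = estimands(build_scenario("3A+", CalibrationConstants(
            b_med_std=0.0, t_total_std=t, c_stab_std=c, d_direct_std=t,
            u_loadings={"U2->IC0": u2, "U2->IC1": u2},
        )))
        assert abs(es2.beta1 - es2.alpha1) < 1e-9
        assert abs(es2.alpha1 - es2.gamma1) < 1e-9


class TestBiasDecomposition:
    def test_scenario_1a_baseline_regression_vanishes(self, scenario_1a):
        bd = bias_decomposition(scenario_1a)
        assert bd.baseline_regression == pytest.approx(0.0, abs=1e-12)
        assert bd.beta1 == pytest.approx(bd.gamma1, abs=1e-12)

    @pytest.mark.parametrize(
        "name,expected_baseline",
        [("2A", 0.351 - 0.119), ("3A", 0.200 - (-0.031))],
    )
    def test_baseline_regression_matches_cell_difference(
        self, scenarios, name, expected_baseline
    ):
        # the published change-score and unadjusted cells differ exactly by
        # the baseline regression of IC0 on WC0 (0.5/2.165 = 0.2309)
        bd = bias_decomposition(scenarios[name])
        assert bd.baseline_regression == pytest.approx(0.5 / 2.165)
        assert bd.baseline_regression == pytest.approx(expected_baseline, abs=0.002)

    @pytest.mark.parametrize("name", ["1A", "1B", "2A", "2B", "3A", "3B", "3A+", "3B+"])
    def test_identity_beta_equals_gamma_minus_baseline(self, scenarios, name):
        bd = bias_decomposition(scenarios[name])
        assert bd.beta1 == pytest.approx(
            bd.gamma1 - bd.baseline_regression, abs=1e-12
        )

    def test_deviations_are_estimand_minus_reference(self, scenario_3a):
        bd = bias_decomposition(scenario_3a)
        es = estimands(scenario_3a)
        assert bd.deviation_from_total["gamma1"] == pytest.approx(0.0, abs=1e-12)
        assert bd.deviation_from_direct["alpha1"] == pytest.approx(0.0, abs=1e-12)
        assert bd.deviation_from_total["beta1"] == pytest.approx(
            es.beta1 - es.total_effect
        )


class TestOldhamCorrelation:
    def test_equal_variance_independent_measures(self):
        assert oldham_correlation(1.0, 1.0, 0.0) == pytest.approx(-1 / math.sqrt(2))

    def test_numerator_vanishes_when_y1_is_y0_plus_noise(self):
        # cov(Y0, Y1) = var(Y0) <=> Y1 = Y0 + independent noise
        assert oldham_correlation(1.0, 1.5, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_unequal_variances(self):
        assert oldham_correlation(1.0, 4.0, 0.0) == pytest.approx(-1 / math.sqrt(5))

    def test_degenerate_difference_rejected(self):
        with pytest.raises(DegenerateDifferenceError):
            oldham_correlation(1.0, 1.0, 1.0)

    @given(
        v0=st.floats(min_value=0.1, max_value=10),
        v1=st.floats(min_value=0.1, max_value=10),
        rho=st.floats(min_value=-0.95, max_value=0.95),
    )
    def test_value_always_in_unit_interval(self, v0, v1, rho):
        r = oldham_correlation(v0, v1, rho * math.sqrt(v0 * v1))
        assert -1.0 <= r <= 1.0


class TestRecommendations:
    @pytest.mark.parametrize(
        "role,sought,analysis,required",
        [
            ("confounder", "total", "followup_adjusted", True),
            ("competing_exposure", "total", "followup_adjusted", False),
            ("mediator", "total", "followup_unadjusted", False),
            ("mediator", "direct", "followup_adjusted", True),
        ],
    )
    def test_analysis_choice(self, role, sought, analysis, required):
        rec = recommend_analysis(role, sought)
        assert rec.analysis == analysis
        assert rec.adjustment_required is required

    def test_every_recommendation_flags_change_scores(self):
        for role in ("competing_exposure", "confounder", "mediator"):
            for sought in ("total", "direct"):
                assert CHANGE_SCORE_WARNING in recommend_analysis(role, sought).warnings

    def test_mediator_direct_carries_confounding_warning(self):
        rec = recommend_analysis("mediator", "direct")
        assert any("mediator-outcome" in w for w in rec.warnings)

    def test_unknown_role_rejected(self):
        with pytest.raises(ChangesimError):
            recommend_analysis("collider")


def test_estimand_table_is_tidy(scenarios):
    tab = estimand_table(scenarios.values())
    assert set(tab.columns) == {
        "scenario", "analysis", "estimand", "value", "causal_reference", "bias"
    }
    assert len(tab) == 8 * 3
    row = tab[(tab.scenario == "3A") & (tab.analysis == "followup_adjusted")].iloc[0]
    assert row["causal_reference"] == pytest.approx(0.05, abs=0.001)
    assert np.isclose(row["bias"], row["value"] - row["causal_reference"])
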