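"""The generated-regressor correction and the group-mean-centering variants."""

import math

import numpy as np
import pytest

from prepost import (
    PrePostDataset,
    apply_correction,
    corrected_residual_variance,
    fit_anova,
    fit_differences,
    fit_dual_centered,
    fit_quasi_ancova,
    hill_variant_analysis,
)
from conftest import random_dataset


class TestCorrectedResidualVariance:
    def test_quasi_recovers_anova_residual_ms(self, worked_example):
        fit = fit_quasi_ancova(worked_example)
        result = corrected_residual_variance(fit, worked_example)
        assert result.corrected_residual_ms == pytest.approx(2.0)
        assert result.df_corrected == 2
        assert result.corrected_se["treatment"] == pytest.approx(math.sqrt(2.0))
        assert "vanishes" in result.substitution_note

    def test_dual_recovers_differences_residual_ms(self, worked_example):
        fit = fit_dual_centered(worked_example)
        result = corrected_residual_variance(fit, worked_example)
        diff = fit_differences(worked_example)
        assert result.corrected_residual_ms == pytest.approx(
            diff.naive_residual_ms, rel=1e-12
        )

    def test_posttest_equal_pretest_zero_residual_limit(self):
        data = PrePostDataset([0, 0, 1, 1], [1.0, 2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 5.0])
        result = corrected_residual_variance(fit_dual_centered(data), data)
        assert result.corrected_residual_ms == pytest.approx(0.0, abs=1e-24)
        assert fit_differences(data).naive_residual_ms == pytest.approx(0.0, abs=1e-24)

    def test_rejects_model_without_generated_regressor(self, worked_example):
        with pytest.raises(ValueError, match="no generated regressor"):
            corrected_residual_variance(fit_anova(worked_example), worked_example)

    def test_model_divisor_flag_uses_fitted_df(self, worked_example):
        fit = fit_quasi_ancova(worked_example)
        ref = corrected_residual_variance(fit, worked_example, divisor="reference")
        alt = corrected_residual_variance(fit, worked_example, divisor="model")
        # same substituted RSS, different divisor: n-2 = 2 vs n-3 = 1
        assert alt.corrected_residual_ms == pytest.approx(
            ref.corrected_residual_ms * ref.df_corrected / alt.df_corrected
        )
        assert alt.df_corrected == fit.df_naive


class TestApplyCorrection:
    def test_only_flagged_coefficients_are_replaced(self, worked_example):
        fit = fit_quasi_ancova(worked_example)
        assert fit.corrected_se["pretest_centered"] == fit.naive_se["pretest_centered"]
        assert fit.corrected_se["treatment"] != fit.naive_se["treatment"]
        assert fit.corrected_se["intercept"] != fit.naive_se["intercept"]

    def test_mismatched_fit_and_result_rejected(self, worked_example):
        quasi = fit_quasi_ancova(worked_example)
        result = corrected_residual_variance(quasi, worked_example)
        with pytest.raises(ValueError, match="applied to"):
            apply_correction(fit_dual_centered(worked_example), result)

    @pytest.mark.parametrize("seed", range(8))
    def test_correction_widens_treatment_se_when_pretest_informative(self, seed):
        """Whenever the centered pretest soaks up real residual variance, the
        naive SE is too small and the corrected one exceeds it."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        t = np.repeat([0.0, 1.0], n)
        pre = rng.normal(100, 10, 2 * n)
        post = 5 + 0.8 * pre + rng.normal(0, 3, 2 * n)
        data = PrePostDataset(t, pre, post)
        fit = fit_quasi_ancova(data)
        assert fit.corrected_se["treatment"] / fit.naive_se["treatment"] > 1.0


class TestEquivalenceSuite:
    """The central analytic claims, exercised across many random datasets."""

    @pytest.mark.parametrize("seed", range(25))
    def test_corrected_centered_models_match_reference_models(self, seed):
        data = random_dataset(np.random.default_rng(1_000 + seed))
        anova, quasi = fit_anova(data), fit_quasi_ancova(data)
        diff, dual = fit_differences(data), fit_dual_centered(data)
        for name in ("intercept", "treatment"):
            assert quasi.coefficients[name] == pytest.approx(
                anova.coefficients[name], rel=1e-10, abs=1e-10
            )
            assert quasi.corrected_se[name] == pytest.approx(
                anova.naive_se[name], rel=1e-10
            )
            assert dual.coefficients[name] == pytest.approx(
                diff.coefficients[name], rel=1e-10, abs=1e-10
            )
            assert dual.corrected_se[name] == pytest.approx(
                diff.naive_se[name], rel=1e-10
            )
        assert quasi.corrected_residual_ms == pytest.approx(
            anova.naive_residual_ms, rel=1e-10
        )
        assert dual.corrected_residual_ms == pytest.approx(
            diff.naive_residual_ms, rel=1e-10
        )


class TestHillVariants:
    @pytest.fixture
    def xyg(self):
        rng = np.random.default_rng(21)
        g = np.repeat([0, 1, 2], 8)
        x = rng.normal(50, 8, g.size)
        y = 2 + 0.5 * x + rng.normal(0, 2, g.size)
        return y, x, g

    def test_variant3_slope_matches_quasi_ancova(self, worked_example):
        fit = hill_variant_analysis(
            worked_example.posttest,
            worked_example.pretest,
            worked_example.treatment,
            variant=3,
        )
        quasi = fit_quasi_ancova(worked_example)
        assert fit.coefficients["predictor_demeaned"] == pytest.approx(
            quasi.coefficients["pretest_centered"], rel=1e-10
        )
        assert all(v == "ols_valid" for v in fit.se_validity.values())

    def test_variant1_reparameterizes_quasi_ancova(self, worked_example):
        """Group mean + demeaned predictor spans {1, treatment, centered}:
        fitted values must coincide with the quasi-ANCOVA fit."""
        quasi = fit_quasi_ancova(worked_example)
        v1 = hill_variant_analysis(
            worked_example.posttest,
            worked_example.pretest,
            worked_example.treatment,
            variant=1,
        )
        fitted_quasi = quasi.response - quasi.residuals
        fitted_v1 = v1.response - v1.residuals
        np.testing.assert_allclose(fitted_v1, fitted_quasi, atol=1e-10)
        assert v1.se_validity["group_mean"] == "needs_2sls"
        assert v1.se_validity["predictor_demeaned"] == "ols_valid"

    def test_variants1_and_2_share_column_space(self, xyg):
        y, x, g = xyg
        v1 = hill_variant_analysis(y, x, g, variant=1)
        v2 = hill_variant_analysis(y, x, g, variant=2)
        np.testing.assert_allclose(v1.residuals, v2.residuals, atol=1e-9)
        assert v2.se_validity["group_mean"] == "needs_2sls"
        assert v2.se_validity["predictor"] == "ols_valid"

    def test_variant2_correction_populates_group_mean_se(self, xyg):
        y, x, g = xyg
        v2 = hill_variant_analysis(y, x, g, variant=2)
        assert v2.corrected_se["group_mean"] != v2.naive_se["group_mean"]
        assert v2.corrected_se["predictor"] == v2.naive_se["predictor"]
        assert v2.df_corrected == y.size - 2

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            hill_variant_analysis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0, 0, 1], variant=1)

    def test_bad_variant_rejected(self, xyg):
        y, x, g = xyg
        with pytest.raises(ValueError, match="variant"):
            hill_variant_analysis(y, x, g, variant=4)
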