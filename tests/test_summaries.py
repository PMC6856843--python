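import numpy as np
import pytest

import threshmeta as tm
from threshmeta.summaries import summary_curve_closed_form

from conftest import point_mass_fit


GRID = np.geomspace(60, 1200, 120)


class TestSummaryCurve:
    def test_point_mass_posterior_reproduces_closed_form(self):
        hp = tm.default_hyperparams()
        fit = point_mass_fit(hp)
        curve = tm.summary_curve(fit, GRID)
        f, t = summary_curve_closed_form(hp, GRID)
        np.testing.assert_allclose(curve.fpr_summary, f, atol=1e-12)
        np.testing.assert_allclose(curve.tpr_summary, t, atol=1e-12)
        # degenerate posterior: CrI collapses onto the curve
        np.testing.assert_allclose(curve.fpr_cri[0], curve.fpr_cri[1], atol=1e-12)

    def test_half_rate_where_mean_equals_transformed_threshold(self):
        hp = tm.HyperParams(m_mu1=np.log(100.0), m_mu2=6.0)
        fit = point_mass_fit(hp)
        curve = tm.summary_curve(fit, np.array([100.0]))
        assert curve.fpr_summary[0] == pytest.approx(0.5)

    def test_monotone_at_every_quantile_level(self, quick_fit):
        curve = tm.summary_curve(quick_fit, GRID)
        for band in (curve.fpr_summary, curve.tpr_summary,
                     curve.fpr_cri[0], curve.fpr_cri[1],
                     curve.tpr_cri[0], curve.tpr_cri[1]):
            assert np.all(np.diff(band) < 0)

    def test_nonpositive_grid_rejected_on_log_scale(self, quick_fit):
        with pytest.raises(ValueError):
            tm.summary_curve(quick_fit, np.array([-5.0, 10.0]))

    def test_extrapolated_grid_points_flagged(self, quick_fit):
        grid = np.geomspace(1.0, 5000.0, 30)
        with pytest.warns(UserWarning, match="extrapolat"):
            curve = tm.summary_curve(quick_fit, grid)
        assert curve.extrapolated.any()


class TestPredictionIntervals:
    def test_pi_contains_cri_under_heterogeneity(self, quick_fit):
        curve = tm.prediction_curve(quick_fit, GRID, seed=0)
        tol = 0.01  # Monte-Carlo slack
        assert np.all(curve.fpr_pi[0] <= curve.fpr_cri[0] + tol)
        assert np.all(curve.fpr_pi[1] >= curve.fpr_cri[1] - tol)
        assert np.all(curve.tpr_pi[0] <= curve.tpr_cri[0] + tol)
        assert np.all(curve.tpr_pi[1] >= curve.tpr_cri[1] - tol)
        assert np.all((curve.fpr_pi >= 0) & (curve.fpr_pi <= 1))
        assert np.all((curve.tpr_pi >= 0) & (curve.tpr_pi <= 1))

    def test_pi_equals_cri_without_heterogeneity(self):
        """All taus zero: a new study is identical to the summary."""
        hp = tm.default_hyperparams()
        hp.tau_mu1 = hp.tau_mu2 = hp.tau_sigma1 = hp.tau_sigma2 = 0.0
        fit = point_mass_fit(hp)
        curve = tm.prediction_curve(fit, GRID, seed=1)
        np.testing.assert_allclose(curve.fpr_pi, curve.fpr_cri, atol=1e-12)
        np.testing.assert_allclose(curve.tpr_pi, curve.tpr_cri, atol=1e-12)

    def test_large_location_heterogeneity_widens_fpr_band(self):
        hp = tm.default_hyperparams()
        hp.tau_mu1 = 1.5
        fit = point_mass_fit(hp, n_draws=2000)
        curve = tm.prediction_curve(fit, GRID, seed=2)
        pi_width = curve.fpr_pi[1] - curve.fpr_pi[0]
        cri_width = curve.fpr_cri[1] - curve.fpr_cri[0] + 1e-12
        low = GRID < 200
        assert np.all(pi_width[low] / cri_width[low] > 1.5)
        assert pi_width[low].max() > 0.3  # heterogeneity is visibly wide, not just relative


class TestSroc:
    def test_equal_populations_give_diagonal(self):
        hp = tm.HyperParams(m_mu1=5.0, m_mu2=5.0, m_sigma1=0.3, m_sigma2=0.3)
        fit = point_mass_fit(hp)
        pairs = tm.sroc_curve(fit, GRID)
        np.testing.assert_allclose(pairs[:, 0], pairs[:, 1], atol=1e-12)

    def test_equal_scales_give_constant_logit_difference(self):
        hp = tm.HyperParams(m_mu1=4.0, m_mu2=6.5, m_sigma1=0.2, m_sigma2=0.2)
        fit = point_mass_fit(hp)
        pairs = tm.sroc_curve(fit, GRID)
        logit = lambda p: np.log(p / (1 - p))
        diff = logit(pairs[:, 1]) - logit(pairs[:, 0])
        np.testing.assert_allclose(diff, diff[0], atol=1e-8)

    def test_endpoints_approach_corners(self):
        fit = point_mass_fit(tm.default_hyperparams())
        wide = np.geomspace(1e-3, 1e7, 300)
        pairs = tm.sroc_curve(fit, wide)
        assert pairs[0, 0] > 0.99 and pairs[0, 1] > 0.99
        assert pairs[-1, 0] < 0.01 and pairs[-1, 1] < 0.01

    def test_coordinates_decrease_along_threshold_order(self, quick_fit):
        pairs = tm.sroc_curve(quick_fit, GRID)
        assert np.all(np.diff(pairs[:, 0]) < 0) and np.all(np.diff(pairs[:, 1]) < 0)


class TestYouden:
    def test_useless_test_has_zero_index(self):
        hp = tm.HyperParams(m_mu1=5.0, m_mu2=5.0)
        fit = point_mass_fit(hp)
        out = tm.youden_optimal(tm.summary_curve(fit, GRID))
        assert out["youden"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_logistic_optimum_is_midpoint(self):
        """Equal scales: J is maximised where g(C) is halfway between the
        population means; with lambda=1, g(C) = C - 1."""
        hp = tm.HyperParams(m_mu1=0.0, m_mu2=2.0, lam=1.0)
        fit = point_mass_fit(
            hp, model=tm.ModelConfig(transform=tm.TransformSpec(mode="fixed", lambda_value=1.0))
        )
        grid = np.linspace(0.5, 4.0, 2001)
        out = tm.youden_optimal(tm.summary_curve(fit, grid))
        assert out["C_opt"] - 1.0 == pytest.approx(1.0, abs=2e-3)

    def test_weighting_sensitivity_lowers_optimal_threshold(self, quick_fit):
        curve = tm.summary_curve(quick_fit, GRID)
        copts = [tm.youden_optimal(curve, w)["C_opt"] for w in (0.3, 0.5, 0.7, 0.9)]
        assert all(b <= a for a, b in zip(copts, copts[1:]))

    def test_invalid_weight_rejected(self, quick_fit):
        with pytest.raises(ValueError):
            tm.youden_optimal(tm.summary_curve(quick_fit, GRID), sens_weight=1.5)


class TestCovariateRatio:
    def _fit_with_alpha(self, alpha=0.0279):
        return point_mass_fit(
            tm.default_hyperparams(), extra={"alpha1_age": alpha}
        )

    def test_known_coefficient_gives_15_percent(self):
        out = tm.covariate_ratio(self._fit_with_alpha(), "age", delta=5.0, group=1)
        assert out["ratio"] == pytest.approx(np.exp(5 * 0.0279), abs=1e-3)
        assert out["ratio"] == pytest.approx(1.15, abs=0.001)

    def test_zero_delta_gives_unit_ratio(self):
        out = tm.covariate_ratio(self._fit_with_alpha(), "age", delta=0.0, group=1)
        assert out["ratio"] == 1.0

    def test_requires_log_transform(self):
        fit = point_mass_fit(
            tm.default_hyperparams(),
            model=tm.ModelConfig(transform=tm.TransformSpec(mode="fixed", lambda_value=0.5)),
            extra={"alpha1_age": 0.03},
        )
        with pytest.raises(ValueError, match="log"):
            tm.covariate_ratio(fit, "age", delta=5.0, group=1)

    def test_unknown_coefficient_rejected(self):
        with pytest.raises(KeyError):
            tm.covariate_ratio(self._fit_with_alpha(), "bmi", delta=1.0, group=1)
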