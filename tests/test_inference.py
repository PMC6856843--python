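import numpy as np
import pytest

import threshmeta as tm
from threshmeta.study_data import DISEASE_FREE, DISEASED


class TestFitBasics:
    def test_dic_identity_holds_exactly(self, quick_fit):
        dic = quick_fit.dic
        assert dic["dic"] == pytest.approx(dic["Dbar"] + dic["pD"], abs=1e-9)
        assert dic["Dbar"] >= 0

    def test_all_hyperparameters_have_draws(self, quick_fit):
        for name in ("m_mu1", "m_mu2", "m_sigma1", "m_sigma2",
                     "tau_mu1", "tau_mu2", "tau_sigma1", "tau_sigma2"):
            assert quick_fit.draws[name].shape == (2, 400)
        assert quick_fit.draws["effects"].shape == (2, 400, 12, 4)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            tm.McmcConfig(seed=None)

    def test_fit_is_reproducible_under_seed(self, small_dataset):
        dataset, _ = small_dataset
        cfg = tm.McmcConfig(chains=1, warmup=50, iterations=50, seed=99)
        a = tm.fit(dataset, tm.ModelConfig(), cfg)
        b = tm.fit(dataset, tm.ModelConfig(), cfg)
        np.testing.assert_array_equal(a.draws["m_mu1"], b.draws["m_mu1"])
        np.testing.assert_array_equal(a.draws["effects"], b.draws["effects"])

    def test_posterior_rates_monotone_in_threshold(self, quick_fit):
        """At every draw, fitted rates decrease strictly with threshold."""
        eff = quick_fit.effects_draws()[::37]  # thin for speed
        grid = tm.boxcox_vec(np.geomspace(50, 1500, 30), 0.0)
        for draw in eff:
            for row in draw:
                fpr = tm.positive_rate(row[0], np.exp(row[2]), grid)
                tpr = tm.positive_rate(row[1], np.exp(row[3]), grid)
                assert np.all(np.diff(fpr) < 0) and np.all(np.diff(tpr) < 0)


class TestSingleStudyFixedEffects:
    def test_posterior_median_fpr_matches_observed_proportion(self):
        """With one study, one threshold and no random effects the model is
        essentially a binomial likelihood: the posterior rate must sit at the
        observed proportion."""
        ds = tm.from_accuracy(400, 400, (100.0,), sens=(0.8,), spec=(0.7,))
        res = tm.fit(
            ds,
            tm.ModelConfig(fixed_effects=True),
            tm.McmcConfig(chains=2, warmup=300, iterations=500, seed=3),
        )
        gc = tm.boxcox(100.0, 0.0)
        fpr = 1 / (1 + np.exp(-(res.stacked("m_mu1") - gc) / np.exp(res.stacked("m_sigma1"))))
        tpr = 1 / (1 + np.exp(-(res.stacked("m_mu2") - gc) / np.exp(res.stacked("m_sigma2"))))
        assert np.median(fpr) == pytest.approx(0.3, abs=0.05)
        assert np.median(tpr) == pytest.approx(0.8, abs=0.05)


class TestShrinkingHeterogeneity:
    def test_taus_concentrate_near_zero_when_generator_has_none(self):
        hp = tm.default_hyperparams()
        hp.tau_mu1 = hp.tau_mu2 = hp.tau_sigma1 = hp.tau_sigma2 = 0.0
        spec = tm.ScenarioSpec(n_studies=12, n_disease_free=(300, 300),
                               n_diseased=(300, 300), thresholds_per_study=(4, 4),
                               hyperparams=hp, seed=17)
        dataset, _ = tm.generate(spec)
        res = tm.fit(dataset, tm.ModelConfig(),
                     tm.McmcConfig(chains=2, warmup=300, iterations=400, seed=2))
        for name in ("tau_mu1", "tau_mu2", "tau_sigma1", "tau_sigma2"):
            assert np.quantile(res.stacked(name), 0.95) < 0.5


class TestDiagnostics:
    def test_report_has_rhat_ess_and_flags(self, quick_fit):
        rep = tm.convergence_report(quick_fit)
        assert {"ess_bulk", "ess_tail", "r_hat", "converged"} <= set(rep.columns)
        assert "m_mu1" in rep.index
        # healthy run: hyperparameters should satisfy the default R-hat bar
        assert rep.loc["m_mu1", "converged"]

    def test_lambda_listed_first_when_estimated(self, small_dataset):
        dataset, _ = small_dataset
        res = tm.fit(
            dataset,
            tm.ModelConfig(transform=tm.TransformSpec(mode="estimated")),
            tm.McmcConfig(chains=2, warmup=150, iterations=150, seed=21),
        )
        assert res.diagnostics.index[0] == "lambda"

    def test_deliberately_short_run_flags_low_ess(self, small_dataset):
        dataset, _ = small_dataset
        res = tm.fit(dataset, tm.ModelConfig(),
                     tm.McmcConfig(chains=2, warmup=10, iterations=30, seed=5))
        rep = res.diagnostics
        assert (rep["ess_bulk"] < 100).any() or (~rep["converged"]).any()


class TestPersistence:
    def test_save_load_round_trip(self, quick_fit, small_dataset, tmp_path):
        dataset, _ = small_dataset
        quick_fit.save(tmp_path / "fit")
        loaded = tm.FitResult.load(tmp_path / "fit")
        np.testing.assert_array_equal(loaded.draws["m_mu1"], quick_fit.draws["m_mu1"])
        assert loaded.model.structure == "independence"
        dic = tm.compute_dic(loaded, dataset)
        assert dic["dic"] == pytest.approx(quick_fit.dic["dic"], abs=1e-6)

    def test_config_echo_is_complete(self, quick_fit):
        echo = quick_fit.config_echo()
        assert echo["model"]["structure"] == "independence"
        assert echo["mcmc"]["seed"] == 1234
        assert echo["priors"]["tau_upper"] == 5.0


class TestMetaRegression:
    def test_age_coefficient_recovered_and_ratio_interpretable(self):
        """A generating age effect on the disease-free location is recovered
        by the meta-regression, and the fitted coefficient converts to a
        multiplicative effect on mean test results (log scale)."""
        hp = tm.default_hyperparams()
        hp.alpha = {1: [0.0279], 2: [0.0279]}
        spec = tm.ScenarioSpec(
            n_studies=25, n_disease_free=(400, 400), n_diseased=(400, 400),
            thresholds_per_study=(4, 4), hyperparams=hp,
            covariates={"age": (50.0, 80.0)}, seed=31,
        )
        dataset, truth = tm.generate(spec)
        assert dataset.covariate_frame().shape == (25, 1)
        res = tm.fit(
            dataset,
            tm.ModelConfig(covariates={1: ["age"], 2: ["age"]}),
            tm.McmcConfig(chains=2, warmup=300, iterations=500, seed=6),
        )
        draws = res.stacked("alpha1_age")
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo <= 0.0279 <= hi
        assert np.median(draws) == pytest.approx(0.0279, abs=0.02)
        out = tm.covariate_ratio(res, "age", delta=5.0, group=1)
        assert out["cri"][0] < out["ratio"] < out["cri"][1]
        assert out["ratio"] == pytest.approx(np.exp(5 * 0.0279), abs=0.15)


class TestStructures:
    @pytest.mark.parametrize("structure", ["structured", "full"])
    def test_correlated_structures_fit_and_store_rhos(self, small_dataset, structure):
        dataset, _ = small_dataset
        res = tm.fit(dataset, tm.ModelConfig(structure=structure),
                     tm.McmcConfig(chains=2, warmup=150, iterations=200, seed=8))
        rho_names = [k for k in res.draws if k.startswith("rho_")]
        assert len(rho_names) == (2 if structure == "structured" else 6)
        for k in rho_names:
            vals = res.stacked(k)
            assert np.all(vals > -1) and np.all(vals < 1)
        assert res.dic["dic"] == pytest.approx(res.dic["Dbar"] + res.dic["pD"])
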