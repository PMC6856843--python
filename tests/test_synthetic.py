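import numpy as np
import pytest
from scipy import stats

import threshmeta as tm
from threshmeta.study_data import DISEASE_FREE, DISEASED
from threshmeta.synthetic import rescale_hyperparams


class TestGenerate:
    def test_same_seed_is_bit_identical(self):
        spec = tm.ScenarioSpec(n_studies=8, missingness=0.2, seed=9)
        d1, t1 = tm.generate(spec)
        d2, t2 = tm.generate(spec)
        assert d1.to_frame().equals(d2.to_frame())
        assert t1 == t2

    def test_counts_monotone_in_every_group(self):
        dataset, _ = tm.generate(tm.ScenarioSpec(n_studies=15, seed=2))
        for rec in dataset.records:
            assert np.all(np.diff(rec.counts_above) <= 0)

    def test_law_of_large_numbers_against_link(self):
        """With no heterogeneity and huge N, observed proportions match the
        logistic link probabilities."""
        hp = tm.default_hyperparams()
        hp.tau_mu1 = hp.tau_mu2 = hp.tau_sigma1 = hp.tau_sigma2 = 0.0
        spec = tm.ScenarioSpec(
            n_studies=3, n_disease_free=(10**6, 10**6), n_diseased=(10**6, 10**6),
            thresholds_per_study=(5, 5), hyperparams=hp, seed=4,
        )
        dataset, _ = tm.generate(spec)
        for rec in dataset.records:
            mu = hp.m_mu1 if rec.group == DISEASE_FREE else hp.m_mu2
            pr = tm.positive_rate(mu, 1.0, tm.boxcox_vec(rec.thresholds, 0.0))
            np.testing.assert_allclose(rec.counts_above / rec.n, pr, atol=0.002)

    def test_missingness_thins_thresholds_but_never_empties(self):
        spec = tm.ScenarioSpec(n_studies=30, thresholds_per_study=(3, 7),
                               missingness=0.6, seed=13)
        dataset, _ = tm.generate(spec)
        assert all(rec.n_thresholds >= 1 for rec in dataset.records)
        sizes = [rec.n_thresholds for rec in dataset.records]
        assert np.mean(sizes) < 5  # thinning actually happened

    def test_truth_record_contains_hyperparams_and_effects(self):
        dataset, truth = tm.generate(tm.ScenarioSpec(n_studies=4, seed=1))
        assert truth["lambda"] == 0.0
        assert set(truth["effects"]) == set(dataset.study_ids)
        assert truth["hyperparams"]["m_mu1"] == pytest.approx(4.6)


class TestIndividualLevel:
    def test_counts_match_raw_results_exactly(self):
        spec = tm.ScenarioSpec(n_studies=4, n_disease_free=(200, 200),
                               n_diseased=(200, 200), seed=6)
        raw, dataset = tm.generate_individual_level(spec)
        for rec in dataset.records:
            y = raw[(rec.study_id, rec.group)]
            expected = (y[:, None] > rec.thresholds[None, :]).sum(axis=0)
            np.testing.assert_array_equal(rec.counts_above, expected)

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_exceedance_matches_link_probability(self, lam):
        """Empirical exceedance agrees with the logistic-link probability."""
        if lam == 0.0:
            hp = tm.default_hyperparams()
            rng_kw = {}
        else:
            # identity-up-to-shift scale: results y = 1 + logistic(mu, sigma),
            # located far enough from the transform boundary at 0
            hp = tm.HyperParams(m_mu1=8.0, m_mu2=14.0, lam=1.0)
            rng_kw = {"threshold_range": (2.0, 20.0)}
        hp.tau_mu1 = hp.tau_mu2 = hp.tau_sigma1 = hp.tau_sigma2 = 0.0
        n = 10**5
        spec = tm.ScenarioSpec(n_studies=1, n_disease_free=(n, n), n_diseased=(n, n),
                               thresholds_per_study=(5, 5), hyperparams=hp, seed=3,
                               **rng_kw)
        raw, dataset = tm.generate_individual_level(spec)
        for rec in dataset.records:
            mu = hp.m_mu1 if rec.group == DISEASE_FREE else hp.m_mu2
            sigma = np.exp(hp.m_sigma1 if rec.group == DISEASE_FREE else hp.m_sigma2)
            pr = tm.positive_rate(mu, sigma, tm.boxcox_vec(rec.thresholds, lam))
            se = np.sqrt(pr * (1 - pr) / n)
            assert np.all(np.abs(rec.counts_above / n - pr) < 3 * se + 1e-12)

    def test_log_scale_results_are_lognormal_like(self):
        """lambda=0: raw results are exp(logistic), so log-results are logistic."""
        hp = tm.default_hyperparams()
        hp.tau_mu1 = hp.tau_mu2 = hp.tau_sigma1 = hp.tau_sigma2 = 0.0
        spec = tm.ScenarioSpec(n_studies=1, n_disease_free=(20_000, 20_000),
                               n_diseased=(10, 10), hyperparams=hp, seed=8)
        raw, dataset = tm.generate_individual_level(spec)
        y = raw[(dataset.study_ids[0], DISEASE_FREE)]
        assert np.all(y > 0)
        logy = np.log(y)
        # logistic(mu, 1) has mean mu and sd pi/sqrt(3)
        assert logy.mean() == pytest.approx(hp.m_mu1, abs=0.05)
        assert logy.std() == pytest.approx(np.pi / np.sqrt(3), abs=0.05)

    def test_two_generation_paths_agree_in_distribution(self):
        """Count-level and individual-level simulation give the same count law."""
        hp = tm.default_hyperparams()
        hp.tau_mu1 = hp.tau_mu2 = hp.tau_sigma1 = hp.tau_sigma2 = 0.0
        spec = tm.ScenarioSpec(
            n_studies=1, n_disease_free=(200, 200), n_diseased=(200, 200),
            thresholds_per_study=(3, 3), ladder_size=3,
            threshold_range=(80.0, 600.0), hyperparams=hp,
        )
        n_rep = 50
        counts_a = np.empty((n_rep, 2, 3))
        counts_b = np.empty((n_rep, 2, 3))
        for r in range(n_rep):
            da, _ = tm.generate(spec, seed=1000 + r)
            _, db = tm.generate_individual_level(spec, seed=5000 + r)
            for g, grp in enumerate((DISEASE_FREE, DISEASED)):
                counts_a[r, g] = da.record(da.study_ids[0], grp).counts_above
                counts_b[r, g] = db.record(db.study_ids[0], grp).counts_above
        rejected = 0
        for g in range(2):
            for t in range(3):
                p = stats.ks_2samp(counts_a[:, g, t], counts_b[:, g, t]).pvalue
                rejected += p < 0.01
        assert rejected <= 1  # allow the occasional expected false positive


class TestScenarioValidation:
    def test_bad_missingness_rejected(self):
        with pytest.raises(ValueError):
            tm.ScenarioSpec(missingness=1.0)

    def test_bad_threshold_range_rejected(self):
        with pytest.raises(ValueError):
            tm.ScenarioSpec(threshold_range=(0.0, 10.0))

    def test_too_many_thresholds_rejected(self):
        with pytest.raises(ValueError):
            tm.ScenarioSpec(thresholds_per_study=(1, 25), ladder_size=20)


def test_rescale_hyperparams_preserves_accuracy_curves():
    """Carrying hyperparams to another lambda leaves summary curves roughly
    unchanged across the reference threshold range (the affine ladder
    alignment is approximate, so agreement is coarse, not exact)."""
    hp0 = tm.default_hyperparams()
    hp1 = rescale_hyperparams(hp0, 0.5)
    grid = np.geomspace(60, 1200, 50)
    f0, t0 = tm.summary_curve_closed_form(hp0, grid)
    f1, t1 = tm.summary_curve_closed_form(hp1, grid)
    assert np.max(np.abs(f0 - f1)) < 0.1
    assert np.max(np.abs(t0 - t1)) < 0.1
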