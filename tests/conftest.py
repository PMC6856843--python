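import numpy as np
import pytest

import threshmeta as tm


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic meta-analysis shared across tests."""
    spec = tm.ScenarioSpec(
        n_studies=12,
        n_disease_free=(100, 300),
        n_diseased=(100, 300),
        thresholds_per_study=(2, 5),
        seed=42,
    )
    dataset, truth = tm.generate(spec)
    return dataset, truth


@pytest.fixture(scope="session")
def quick_fit(small_dataset):
    """A short but converged independence-model fit, reused where tests only
    need *a* posterior rather than a precise one."""
    dataset, _ = small_dataset
    return tm.fit(
        dataset,
        tm.ModelConfig(structure="independence"),
        tm.McmcConfig(chains=2, warmup=300, iterations=400, seed=1234),
    )


def point_mass_fit(hp: tm.HyperParams, model: tm.ModelConfig | None = None,
                   n_draws: int = 50, extra: dict | None = None) -> tm.FitResult:
    """A degenerate FitResult whose every draw equals the given hyperparams.

    Used to check that posterior summaries reduce to their closed forms when
    the posterior is a point mass.
    """
    model = model or tm.ModelConfig()
    names = {
        "m_mu1": hp.m_mu1, "m_mu2": hp.m_mu2,
        "m_sigma1": hp.m_sigma1, "m_sigma2": hp.m_sigma2,
        "tau_mu1": hp.tau_mu1, "tau_mu2": hp.tau_mu2,
        "tau_sigma1": hp.tau_sigma1, "tau_sigma2": hp.tau_sigma2,
    }
    draws = {k: np.full((2, n_draws), v) for k, v in names.items()}
    if hp.lam is not None and model.transform.estimated:
        draws["lambda"] = np.full((2, n_draws), hp.lam)
    for k, v in (extra or {}).items():
        draws[k] = np.full((2, n_draws), v)
    effects = np.tile(
        np.array([hp.m_mu1, hp.m_mu2, hp.m_sigma1, hp.m_sigma2]), (2, n_draws, 1, 1)
    )
    draws["effects"] = effects
    return tm.FitResult(
        draws=draws,
        study_ids=["study_01"],
        model=model,
        mcmc=tm.McmcConfig(chains=2, warmup=0, iterations=n_draws, seed=0),
        prior=tm.PriorConfig(),
    )
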