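"""Bayesian fitting of the multi-threshold accuracy model, convergence
diagnostics and the Deviance Information Criterion.

``fit`` runs several independent MCMC chains of the sampler in
:mod:`threshmeta._mcmc` and returns a :class:`FitResult` holding the joint
posterior draws of all hyperparameters and study effects, per-parameter
R-hat / effective sample size, and the DIC.

The DIC uses the residual deviance of the conditional binomial
factorisation: Dbar is the posterior mean deviance, the plug-in deviance
is evaluated at the posterior means of the conditional binomial
probabilities (the direct parents of the likelihood), pD = Dbar - Dplug
and DIC = Dbar + pD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from . import _mcmc, between_study as bs
from .study_data import MetaDataset
from .transform import TransformSpec

_HYPER_NAMES = ("m_mu1", "m_mu2", "m_sigma1", "m_sigma2",
                "tau_mu1", "tau_mu2", "tau_sigma1", "tau_sigma2")


@dataclass
class ModelConfig:
    """Model block: correlation structure, transform, covariates."""

    structure: str = "independence"
    transform: TransformSpec = field(default_factory=TransformSpec)
    covariates: dict = field(default_factory=dict)  # target r -> [names]
    center_covariates: bool = True
    fixed_effects: bool = False

    def __post_init__(self):
        if self.structure not in bs.STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        self.covariates = {int(r): list(v) for r, v in self.covariates.items()}
        for r in self.covariates:
            if r not in (1, 2, 3, 4):
                raise ValueError("covariate targets must be in 1..4")


@dataclass
class McmcConfig:
    chains: int = 4
    warmup: int = 1000
    iterations: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("an explicit MCMC seed is required for reproducibility")
        if self.chains < 1 or self.warmup < 0 or self.iterations < 1:
            raise ValueError("invalid MCMC run lengths")


@dataclass
class FitResult:
    """Posterior draws, diagnostics, and DIC for one fitted model."""

    draws: dict  # name -> (chains, iterations, ...) arrays
    study_ids: list
    model: ModelConfig
    mcmc: McmcConfig
    prior: bs.PriorConfig
    diagnostics: pd.DataFrame | None = None
    dic: dict | None = None
    prepared: _mcmc.Prepared | None = None

    # -- accessors --------------------------------------------------------

    @property
    def n_chains(self) -> int:
        return self.draws["m_mu1"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["m_mu1"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter flattened across chains."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def hyper_draws(self) -> dict:
        out = {k: self.stacked(k) for k in self.draws if k != "effects"}
        return out

    def effects_draws(self) -> np.ndarray:
        """(total draws, studies, 4) study-effect draws."""
        return self.stacked("effects")

    def lambda_draws(self) -> np.ndarray:
        if "lambda" in self.draws:
            return self.stacked("lambda")
        lam = self.model.transform.lambda_value
        return np.full(self.n_chains * self.n_draws, lam)

    def to_inference_data(self) -> az.InferenceData:
        data = {k: v for k, v in self.draws.items() if k != "effects"}
        eff = self.draws["effects"]
        for j, nm in enumerate(("mu1", "mu2", "lsigma1", "lsigma2")):
            data[nm] = eff[..., j]
        coords = {"study": self.study_ids}
        dims = {nm: ["study"] for nm in ("mu1", "mu2", "lsigma1", "lsigma2")}
        return az.from_dict(posterior=data, coords=coords, dims=dims)

    def config_echo(self) -> dict:
        return {
            "model": {
                "structure": self.model.structure,
                "transform": asdict(self.model.transform),
                "covariates": {str(k): v for k, v in self.model.covariates.items()},
                "center_covariates": self.model.center_covariates,
                "fixed_effects": self.model.fixed_effects,
            },
            "priors": asdict(self.prior),
            "mcmc": {k: getattr(self.mcmc, k) for k in ("chains", "warmup", "iterations", "seed")},
        }

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        """Persist draws (npz), diagnostics (CSV), DIC and config (JSON)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "draws.npz", **self.draws)
        (directory / "study_ids.json").write_text(json.dumps(self.study_ids))
        if self.diagnostics is not None:
            self.diagnostics.to_csv(directory / "diagnostics.csv")
        if self.dic is not None:
            (directory / "dic.json").write_text(json.dumps(self.dic, indent=2))
        (directory / "config.json").write_text(json.dumps(self.config_echo(), indent=2))

    @classmethod
    def load(cls, directory) -> "FitResult":
        directory = Path(directory)
        with np.load(directory / "draws.npz") as z:
            draws = {k: z[k] for k in z.files}
        cfg = json.loads((directory / "config.json").read_text())
        model = ModelConfig(
            structure=cfg["model"]["structure"],
            transform=TransformSpec(**cfg["model"]["transform"]),
            covariates={int(k): v for k, v in cfg["model"]["covariates"].items()},
            center_covariates=cfg["model"]["center_covariates"],
            fixed_effects=cfg["model"]["fixed_effects"],
        )
        mcmc = McmcConfig(**cfg["mcmc"])
        prior = bs.PriorConfig(
            mean_sd=cfg["priors"]["mean_sd"],
            tau_upper=cfg["priors"]["tau_upper"],
            rho_bounds=tuple(cfg["priors"]["rho_bounds"]),
        )
        diag_path = directory / "diagnostics.csv"
        diagnostics = pd.read_csv(diag_path, index_col=0) if diag_path.exists() else None
        dic_path = directory / "dic.json"
        dic = json.loads(dic_path.read_text()) if dic_path.exists() else None
        study_ids = json.loads((directory / "study_ids.json").read_text())
        return cls(draws=draws, study_ids=study_ids, model=model, mcmc=mcmc,
                   prior=prior, diagnostics=diagnostics, dic=dic)


def fit(
    dataset: MetaDataset,
    model: ModelConfig | None = None,
    mcmc: McmcConfig | None = None,
    prior: bs.PriorConfig | None = None,
) -> FitResult:
    """Fit the hierarchical multi-threshold model by MCMC.

    Returns a :class:`FitResult` with draws for every active parameter,
    R-hat / ESS diagnostics (non-convergence is flagged, not fatal) and
    the DIC.  Reproducible under a fixed seed.
    """
    model = model or ModelConfig()
    mcmc = mcmc or McmcConfig(seed=0)
    prior = prior or bs.PriorConfig()
    if model.transform.estimated and np.any([r.thresholds.min() <= 0 for r in dataset.records]):
        raise ValueError("Box-Cox estimation requires strictly positive thresholds")
    prep = _mcmc.prepare(dataset, model.covariates or None, model.center_covariates)
    S = prep.n_studies
    rho_keys = bs.RHO_KEYS[model.structure]
    n_it = mcmc.iterations

    store: dict[str, np.ndarray] = {
        name: np.empty((mcmc.chains, n_it)) for name in _HYPER_NAMES
    }
    for k in rho_keys:
        store[f"rho_{k}"] = np.empty((mcmc.chains, n_it))
    coef_names = []
    for r in sorted(model.covariates):
        for nm in model.covariates[r]:
            coef_names.append(f"alpha{r}_{nm}")
    for nm in coef_names:
        store[nm] = np.empty((mcmc.chains, n_it))
    if model.transform.estimated:
        store["lambda"] = np.empty((mcmc.chains, n_it))
    store["effects"] = np.empty((mcmc.chains, n_it, S, 4))

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        sampler = _mcmc.Sampler(prep, model.structure, model.transform, prior,
                                rng, fixed_effects=model.fixed_effects)

        def record(i, st, c=c, sampler=sampler):
            for j, name in enumerate(_HYPER_NAMES[:4]):
                store[name][c, i] = st.theta[j]
            for j, name in enumerate(_HYPER_NAMES[4:]):
                store[name][c, i] = st.tau[j]
            for j, k in enumerate(rho_keys):
                store[f"rho_{k}"][c, i] = st.rho[j]
            pos = 4
            for nm in coef_names:
                store[nm][c, i] = st.theta[pos]
                pos += 1
            if model.transform.estimated:
                store["lambda"][c, i] = st.lam
            store["effects"][c, i] = st.effects

        sampler.run(mcmc.warmup, n_it, record)

    result = FitResult(draws=store, study_ids=prep.study_ids, model=model,
                       mcmc=mcmc, prior=prior, prepared=prep)
    result.diagnostics = convergence_report(result)
    result.dic = compute_dic(result, dataset)
    return result


def _row_quantities(fit: FitResult, prep: _mcmc.Prepared):
    """Conditional binomial probabilities for every draw x data row."""
    eff = fit.effects_draws()  # (D, S, 4)
    lam = fit.lambda_draws()  # (D,)
    logc = np.log(prep.thresholds)[None, :]
    lam_col = lam[:, None]
    small = np.abs(lam_col) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(small, logc, np.expm1(np.where(small, 1.0, lam_col) * logc)
                      / np.where(small, 1.0, lam_col))
    mu = eff[:, prep.study_idx, prep.group_idx]
    s = np.exp(eff[:, prep.study_idx, 2 + prep.group_idx])
    from scipy.special import expit

    pr = np.clip(expit((mu - gc) / s), _mcmc._P_CLIP, 1 - _mcmc._P_CLIP)
    p = pr.copy()
    idx = np.flatnonzero(~prep.first)
    p[:, idx] = np.clip(pr[:, idx] / pr[:, idx - 1], _mcmc._P_CLIP, 1 - _mcmc._P_CLIP)
    return p


def compute_dic(fit: FitResult, dataset: MetaDataset | None = None) -> dict:
    """Deviance Information Criterion from the stored posterior draws."""
    prep = fit.prepared
    if prep is None:
        if dataset is None:
            raise ValueError("compute_dic needs the dataset when the fit was reloaded")
        prep = _mcmc.prepare(dataset, fit.model.covariates or None,
                             fit.model.center_covariates)
        fit.prepared = prep
    p = _row_quantities(fit, prep)
    dev = _mcmc.deviance_rows(prep, p).sum(axis=1)
    dbar = float(dev.mean())
    p_mean = p.mean(axis=0)
    dplug = float(_mcmc.deviance_rows(prep, p_mean).sum())
    pd_eff = dbar - dplug
    out = {"Dbar": dbar, "pD": pd_eff, "dic": dbar + pd_eff}
    if pd_eff < 0:
        out["warning"] = "pD < 0: known DIC pathology for this posterior"
        warnings.warn(out["warning"])
    return out


def convergence_report(fit: FitResult, rhat_limit: float = 1.05) -> pd.DataFrame:
    """Per-parameter R-hat and effective sample size with pass/fail flags.

    The Box-Cox parameter, when estimated, is listed first: it is the
    parameter most prone to high autocorrelation, so its ESS deserves
    prominence.  With a single chain R-hat is not defined and only ESS is
    reported.
    """
    idata = fit.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summ = az.summary(idata, kind="diagnostics")
    df = summ[["ess_bulk", "ess_tail", "r_hat"]].copy()
    if fit.n_chains < 2:
        df["r_hat"] = np.nan
    df["converged"] = (df["r_hat"] < rhat_limit) | df["r_hat"].isna()
    if "lambda" in df.index:
        df = df.reindex(["lambda"] + [i for i in df.index if i != "lambda"])
    return df
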