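"""Between-study models for the four sets of random effects.

Across studies, the study-level parameters (mu_i1, mu_i2, log sigma_i1,
log sigma_i2) are modelled as quadrivariate normal with means
(m_mu1, m_mu2, m_sigma1, m_sigma2) and between-study SDs
(tau_mu1, tau_mu2, tau_sigma1, tau_sigma2).  Three correlation structures
are supported:

``full``
    all six pairwise correlations free (rho_mu, rho_mu1s1, rho_mu1s2,
    rho_mu2s1, rho_mu2s2, rho_sigma), subject to positive definiteness;
``structured``
    two free correlations — rho_mu between the two locations, and a common
    rho_mu_sigma between each location and its own log-scale; all other
    correlations are induced, never free.  The joint law factorises into
    four conditionally independent univariate normals
    (mu_i1; mu_i2 | mu_i1; log sigma_ij | mu_ij), which is also how draws
    are generated;
``independence``
    four independent sets of random effects (all correlations zero).

Study-level covariates shift the means: the r-th component of the mean
becomes m_r + alpha_r' z_ir (meta-regression).  Covariates are typically
mean-centered before entering the model (handled upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .likelihood import StudyEffects
from .transform import TransformSpec

STRUCTURES = ("full", "structured", "independence")

#: free correlation parameters of each structure, in canonical order.
#: component order of the random-effect vector is
#: (mu_1, mu_2, log sigma_1, log sigma_2).
RHO_KEYS = {
    "full": ("mu", "mu1_sigma1", "mu1_sigma2", "mu2_sigma1", "mu2_sigma2", "sigma"),
    "structured": ("mu", "mu_sigma"),
    "independence": (),
}

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class HyperParams:
    """Population-level parameters of the hierarchical model."""

    m_mu1: float = 0.0
    m_mu2: float = 0.0
    m_sigma1: float = 0.0
    m_sigma2: float = 0.0
    tau_mu1: float = 0.0
    tau_mu2: float = 0.0
    tau_sigma1: float = 0.0
    tau_sigma2: float = 0.0
    rho: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)  # target r (1..4) -> coefficient array
    lam: float | None = None

    def __post_init__(self):
        for name in ("tau_mu1", "tau_mu2", "tau_sigma1", "tau_sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for key, r in self.rho.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation {key}={r} outside (-1, 1)")
        self.alpha = {int(r): np.atleast_1d(np.asarray(a, float)) for r, a in self.alpha.items()}

    @property
    def means(self) -> np.ndarray:
        return np.array([self.m_mu1, self.m_mu2, self.m_sigma1, self.m_sigma2])

    @property
    def taus(self) -> np.ndarray:
        return np.array([self.tau_mu1, self.tau_mu2, self.tau_sigma1, self.tau_sigma2])


@dataclass
class PriorConfig:
    """Hyperprior settings.

    Defaults: Normal(0, mean_sd^2) on means and meta-regression
    coefficients (mean_sd = 10), Uniform(0, tau_upper) on between-study
    SDs (tau_upper = 5), Uniform(-1, 1) on correlations.
    """

    mean_sd: float = 10.0
    tau_upper: float = 5.0
    rho_bounds: tuple = (-1.0, 1.0)

    def __post_init__(self):
        if self.mean_sd <= 0 or self.tau_upper <= 0:
            raise ValueError("prior scales must be positive")
        if not self.rho_bounds[0] < self.rho_bounds[1]:
            raise ValueError("rho bounds must be ordered")


@dataclass(frozen=True)
class Prior:
    name: str
    dist: str  # "normal" | "uniform"
    args: tuple


@dataclass
class PriorSet:
    priors: list

    def __len__(self):
        return len(self.priors)

    def names(self):
        return [p.name for p in self.priors]


def build_prior(
    config: PriorConfig,
    structure: str,
    n_covariates: int = 0,
    transform: TransformSpec | None = None,
) -> PriorSet:
    """Assemble the prior set active under a correlation structure."""
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    priors = [
        Prior(name, "normal", (0.0, config.mean_sd))
        for name in ("m_mu1", "m_mu2", "m_sigma1", "m_sigma2")
    ]
    priors += [
        Prior(name, "uniform", (0.0, config.tau_upper))
        for name in ("tau_mu1", "tau_mu2", "tau_sigma1", "tau_sigma2")
    ]
    priors += [Prior(f"rho_{k}", "uniform", config.rho_bounds) for k in RHO_KEYS[structure]]
    priors += [
        Prior(f"alpha_{i}", "normal", (0.0, config.mean_sd)) for i in range(n_covariates)
    ]
    if transform is not None and transform.estimated:
        priors.append(Prior("lambda", "uniform", (transform.prior_low, transform.prior_high)))
    return PriorSet(priors)


def correlation_matrix(hp: HyperParams, structure: str) -> np.ndarray:
    """4x4 correlation matrix implied by the structure's free parameters."""
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    R = np.eye(4)
    if structure == "full":
        rho = {k: hp.rho.get(k, 0.0) for k in RHO_KEYS["full"]}
        R[0, 1] = R[1, 0] = rho["mu"]
        R[0, 2] = R[2, 0] = rho["mu1_sigma1"]
        R[0, 3] = R[3, 0] = rho["mu1_sigma2"]
        R[1, 2] = R[2, 1] = rho["mu2_sigma1"]
        R[1, 3] = R[3, 1] = rho["mu2_sigma2"]
        R[2, 3] = R[3, 2] = rho["sigma"]
    elif structure == "structured":
        rm = hp.rho.get("mu", 0.0)
        rms = hp.rho.get("mu_sigma", 0.0)
        # induced correlations of the conditional factorisation
        R[0, 1] = R[1, 0] = rm
        R[0, 2] = R[2, 0] = rms
        R[1, 3] = R[3, 1] = rms
        R[0, 3] = R[3, 0] = rm * rms
        R[1, 2] = R[2, 1] = rm * rms
        R[2, 3] = R[3, 2] = rm * rms * rms
    return R


def covariance_matrix(hp: HyperParams, structure: str) -> np.ndarray:
    taus = hp.taus
    return correlation_matrix(hp, structure) * np.outer(taus, taus)


def mean_shift(hp: HyperParams, covariates: dict | None) -> np.ndarray:
    """Covariate contribution alpha_r' z_ir to each mean component."""
    shift = np.zeros(4)
    if covariates:
        for r, z in covariates.items():
            a = hp.alpha.get(int(r))
            if a is None:
                raise ValueError(f"covariates supplied for target {r} but no coefficients")
            z = np.atleast_1d(np.asarray(z, float))
            shift[int(r) - 1] = float(a @ z)
    return shift


def _chol_or_raise(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("between-study covariance matrix is not positive definite")


def mvn_logpdf_rows(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise MVN log-density for a common covariance (sampler hot path)."""
    L = _chol_or_raise(cov)
    diff = np.atleast_2d(x) - np.atleast_2d(mean)
    sol = linalg.solve_triangular(L, diff.T, lower=True)
    return -0.5 * np.sum(sol**2, axis=0) - np.sum(np.log(np.diag(L))) - 2.0 * _LOG_2PI


def random_effects_logpdf(
    effects: StudyEffects,
    hp: HyperParams,
    structure: str,
    covariates: dict | None = None,
) -> float:
    """Log-density of one study's (mu_1, mu_2, log sigma_1, log sigma_2).

    ``covariates`` maps target index r (1..4) to that study's covariate
    vector z_ir; coefficients come from ``hp.alpha``.
    """
    v = np.array(
        [effects.mu1, effects.mu2, math.log(effects.sigma1), math.log(effects.sigma2)]
    )
    mean = hp.means + mean_shift(hp, covariates)
    cov = covariance_matrix(hp, structure)
    return float(mvn_logpdf_rows(v, mean, cov)[0])


def sample_effects_matrix(
    hp: HyperParams,
    structure: str,
    n: int,
    rng: np.random.Generator,
    covariates: dict | None = None,
) -> np.ndarray:
    """Draw (n, 4) study-effect vectors (mu_1, mu_2, log sigma_1, log sigma_2).

    The structured model is sampled through its exact conditional
    decomposition; the full model through the Cholesky factor of its dense
    covariance; independence componentwise.
    """
    mean = hp.means + mean_shift(hp, covariates)
    taus = hp.taus
    if structure == "structured":
        rm = hp.rho.get("mu", 0.0)
        rms = hp.rho.get("mu_sigma", 0.0)
        out = np.empty((n, 4))
        out[:, 0] = mean[0] + taus[0] * rng.standard_normal(n)
        cond_mean = mean[1] + _safe_ratio(taus[1], taus[0]) * rm * (out[:, 0] - mean[0])
        out[:, 1] = cond_mean + math.sqrt(1.0 - rm**2) * taus[1] * rng.standard_normal(n)
        for j in (0, 1):
            cm = mean[2 + j] + _safe_ratio(taus[2 + j], taus[j]) * rms * (out[:, j] - mean[j])
            out[:, 2 + j] = cm + math.sqrt(1.0 - rms**2) * taus[2 + j] * rng.standard_normal(n)
        return out
    cov = covariance_matrix(hp, structure)
    if np.all(taus == 0):
        return np.tile(mean, (n, 1))
    if structure == "independence":
        return mean + taus * rng.standard_normal((n, 4))
    L = _chol_or_raise(cov + 1e-12 * np.eye(4))
    return mean + rng.standard_normal((n, 4)) @ L.T


def _safe_ratio(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def sample_study_effects(
    hp: HyperParams,
    structure: str,
    covariates: dict | None = None,
    n: int = 1,
    seed=None,
) -> list[StudyEffects]:
    """Draw new-study effects; used for prediction intervals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = sample_effects_matrix(hp, structure, n, rng, covariates)
    return [
        StudyEffects(mu1=row[0], mu2=row[1], sigma1=math.exp(row[2]), sigma2=math.exp(row[3]))
        for row in mat
    ]
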