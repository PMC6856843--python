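"""Sampler internals for the hierarchical multi-threshold accuracy model.

The posterior is explored with a Metropolis-within-Gibbs scheme designed
around the structure of the model:

* study effects (mu_i1, mu_i2, log sigma_i1, log sigma_i2) — vectorised
  random-walk Metropolis, one coordinate at a time across all studies
  simultaneously, with per-study proposal scales adapted during warmup;
* population means and meta-regression coefficients — exact conjugate
  (Gibbs) draw from their multivariate-normal full conditional;
* between-study SDs — univariate slice sampling in the centered
  parameterisation, interleaved with a non-centered (ancillarity-
  sufficiency interweaving) slice step that keeps the standardised
  residuals fixed; the pair mixes well both when heterogeneity is large
  and when it is near zero;
* correlations — univariate slice sampling (positive definiteness of the
  full-structure covariance is enforced by rejection: a non-PD proposal
  has log-density -inf);
* the Box-Cox parameter lambda — univariate slice sampling, plus a joint
  Metropolis move that changes lambda while applying the compensating
  affine map to all location/scale parameters (an exactly invertible
  deterministic transport with its Jacobian in the acceptance ratio).
  The joint move targets the strong posterior coupling between lambda and
  the location parameters, which otherwise produces very high
  autocorrelation in lambda.

Everything operates on a flattened row representation of the dataset, so
one likelihood evaluation is a handful of numpy operations regardless of
how many studies or thresholds there are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, xlogy

from . import between_study as bs
from .study_data import MetaDataset, conditional_counts
from .transform import TransformSpec

_P_CLIP = 1e-12
_TAU_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# flattened data representation


@dataclass
class Prepared:
    """Dataset flattened to row arrays for vectorised likelihood evaluation."""

    study_ids: list
    study_idx: np.ndarray  # (R,) int
    group_idx: np.ndarray  # (R,) int in {0,1}
    thresholds: np.ndarray  # (R,) float, raw scale
    trials: np.ndarray  # (R,) int
    succ: np.ndarray  # (R,) int
    first: np.ndarray  # (R,) bool — first threshold of its (study, group) run
    logcoef: np.ndarray  # (R,) binomial coefficients
    cov_targets: dict  # r -> (names, Z (S, p_r)) centered design
    n_studies: int

    _gc_cache: tuple = field(default=None, repr=False)

    def g_thresholds(self, lam: float) -> np.ndarray:
        if self._gc_cache is not None and self._gc_cache[0] == lam:
            return self._gc_cache[1]
        logc = np.log(self.thresholds)
        gc = logc if abs(lam) < 1e-8 else np.expm1(lam * logc) / lam
        object.__setattr__(self, "_gc_cache", (lam, gc))
        return gc

    @property
    def n_rows(self) -> int:
        return self.study_idx.size


def prepare(dataset: MetaDataset, covariates: dict | None = None, center: bool = True) -> Prepared:
    """Flatten a dataset (and optional covariate selection) for the sampler.

    ``covariates`` maps target index r (1..4) to a list of covariate
    column names; designs are mean-centered by default.
    """
    ids = dataset.study_ids
    pos = {sid: i for i, sid in enumerate(ids)}
    study_idx, group_idx, thr, trials, succ, first = [], [], [], [], [], []
    for rec in dataset.records:
        pairs = conditional_counts(rec)
        for t, (n_t, x_t) in enumerate(pairs):
            study_idx.append(pos[rec.study_id])
            group_idx.append(rec.group - 1)
            thr.append(rec.thresholds[t])
            trials.append(n_t)
            succ.append(x_t)
            first.append(t == 0)
    trials = np.asarray(trials, dtype=float)
    succ = np.asarray(succ, dtype=float)
    logcoef = gammaln(trials + 1) - gammaln(succ + 1) - gammaln(trials - succ + 1)
    cov_targets = {}
    if covariates:
        frame = dataset.covariate_frame()
        if frame is None:
            raise ValueError("model requests covariates but the dataset has none")
        frame = frame.loc[ids]
        for r, names in covariates.items():
            names = list(names)
            missing = [n for n in names if n not in frame.columns]
            if missing:
                raise ValueError(f"unknown covariates {missing}")
            Z = frame[names].to_numpy(dtype=float)
            if center:
                Z = Z - Z.mean(axis=0)
            cov_targets[int(r)] = (names, Z)
    return Prepared(
        study_ids=ids,
        study_idx=np.asarray(study_idx),
        group_idx=np.asarray(group_idx),
        thresholds=np.asarray(thr, dtype=float),
        trials=trials,
        succ=succ,
        first=np.asarray(first),
        logcoef=logcoef,
        cov_targets=cov_targets,
        n_studies=len(ids),
    )


def row_rates(prep: Prepared, effects: np.ndarray, lam: float) -> np.ndarray:
    """Marginal positive-test probability for every data row."""
    gc = prep.g_thresholds(lam)
    mu = effects[prep.study_idx, prep.group_idx]
    s = np.exp(effects[prep.study_idx, 2 + prep.group_idx])
    return np.clip(expit((mu - gc) / s), _P_CLIP, 1.0 - _P_CLIP)


def conditional_rates(prep: Prepared, pr: np.ndarray) -> np.ndarray:
    p = pr.copy()
    idx = ~prep.first
    p[idx] = np.clip(pr[idx] / pr[np.flatnonzero(idx) - 1], _P_CLIP, 1.0 - _P_CLIP)
    return p


def loglik_rows(prep: Prepared, effects: np.ndarray, lam: float) -> np.ndarray:
    """Per-row conditional-binomial log-likelihood."""
    p = conditional_rates(prep, row_rates(prep, effects, lam))
    return prep.logcoef + prep.succ * np.log(p) + (prep.trials - prep.succ) * np.log1p(-p)


def loglik_per_study(prep: Prepared, effects: np.ndarray, lam: float) -> np.ndarray:
    return np.bincount(prep.study_idx, loglik_rows(prep, effects, lam), minlength=prep.n_studies)


def loglik_total(prep: Prepared, effects: np.ndarray, lam: float) -> float:
    return float(loglik_rows(prep, effects, lam).sum())


def deviance_rows(prep: Prepared, p: np.ndarray) -> np.ndarray:
    n, x = prep.trials, prep.succ
    term = xlogy(x, x) - xlogy(x, n * p) + xlogy(n - x, n - x) - xlogy(n - x, n - n * p)
    return 2.0 * np.where(n > 0, term, 0.0)


def deviance_of_effects(prep: Prepared, effects: np.ndarray, lam: float) -> float:
    p = conditional_rates(prep, row_rates(prep, effects, lam))
    return float(deviance_rows(prep, p).sum())


# ---------------------------------------------------------------------------
# slice sampling (Neal 2003, stepping out + shrinkage)


def slice_sample(x0, logf, lo, hi, w, rng, max_steps=30):
    f0 = logf(x0)
    if not np.isfinite(f0):
        return x0, f0
    y = f0 - rng.exponential()
    u = rng.uniform()
    left = max(lo, x0 - w * u)
    right = min(hi, left + w)
    steps = max_steps
    while left > lo and steps > 0 and logf(left) > y:
        left = max(lo, left - w)
        steps -= 1
    steps = max_steps
    while right < hi and steps > 0 and logf(right) > y:
        right = min(hi, right + w)
        steps -= 1
    for _ in range(100):
        x1 = rng.uniform(left, right)
        f1 = logf(x1)
        if f1 > y:
            return x1, f1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0, f0


# ---------------------------------------------------------------------------
# sampler state and updates


@dataclass
class ChainState:
    effects: np.ndarray  # (S, 4)
    theta: np.ndarray  # (4 + n_coef,) population means + coefficients
    tau: np.ndarray  # (4,)
    rho: np.ndarray  # per-structure free correlations
    lam: float


class Sampler:
    """One-chain Gibbs/Metropolis sampler for the assembled model."""

    def __init__(self, prep, structure, transform, prior, rng,
                 fixed_effects=False):
        self.prep = prep
        self.structure = structure
        self.transform = transform
        self.prior = prior
        self.rng = rng
        self.fixed_effects = fixed_effects
        self.rho_keys = bs.RHO_KEYS[structure]
        # theta layout: 4 means, then coefficient blocks per sorted target r
        self.coef_slices = {}
        p = 4
        for r in sorted(prep.cov_targets):
            names, Z = prep.cov_targets[r]
            self.coef_slices[r] = slice(p, p + Z.shape[1])
            p += Z.shape[1]
        self.n_theta = p
        S = prep.n_studies
        self.W = np.zeros((S, 4, p))
        self.W[:, np.arange(4), np.arange(4)] = 1.0
        for r, sl in self.coef_slices.items():
            self.W[:, r - 1, sl] = prep.cov_targets[r][1]
        # adaptation state
        self.eff_scale = np.full((S, 4), 0.5)
        self.lam_scale = 0.2
        self._adapt_t = 0
        # reference thresholds of the lambda rescaling move
        self.c_lo = float(prep.thresholds.min())
        self.c_hi = float(prep.thresholds.max())
        self._distinct_thresholds = np.unique(prep.thresholds)

    # -- parameter bookkeeping -------------------------------------------

    def hyperparams(self, st: ChainState) -> bs.HyperParams:
        alpha = {r: st.theta[sl].copy() for r, sl in self.coef_slices.items()}
        return bs.HyperParams(
            m_mu1=st.theta[0], m_mu2=st.theta[1],
            m_sigma1=st.theta[2], m_sigma2=st.theta[3],
            tau_mu1=st.tau[0], tau_mu2=st.tau[1],
            tau_sigma1=st.tau[2], tau_sigma2=st.tau[3],
            rho=dict(zip(self.rho_keys, st.rho)),
            alpha=alpha,
            lam=st.lam if self.transform.estimated else None,
        )

    def mean_matrix(self, theta: np.ndarray) -> np.ndarray:
        """(S, 4) per-study random-effect means m + alpha'z."""
        return self.W @ theta

    def _cov(self, st: ChainState) -> np.ndarray:
        hp = bs.HyperParams(
            tau_mu1=st.tau[0], tau_mu2=st.tau[1],
            tau_sigma1=st.tau[2], tau_sigma2=st.tau[3],
            rho=dict(zip(self.rho_keys, st.rho)),
        )
        return bs.covariance_matrix(hp, self.structure)

    def re_logpdf(self, st: ChainState, effects=None, cov=None):
        """Per-study random-effects log-density (vector of length S)."""
        E = st.effects if effects is None else effects
        M = self.mean_matrix(st.theta)
        if cov is None:
            cov = self._cov(st)
        try:
            return bs.mvn_logpdf_rows(E, M, cov)
        except (ValueError, np.linalg.LinAlgError):
            return np.full(self.prep.n_studies, -np.inf)

    # -- initialisation ---------------------------------------------------

    def initial_state(self) -> ChainState:
        prep, rng = self.prep, self.rng
        lam0 = self.transform.lambda_value if not self.transform.estimated else float(
            np.clip(0.0, self.transform.prior_low + 0.1, self.transform.prior_high - 0.1)
        )
        gc = prep.g_thresholds(lam0)
        S = prep.n_studies
        E = np.zeros((S, 4))
        p_emp = (prep.succ_marginal + 0.5) / (prep.n_marginal + 1.0)
        z = np.log(p_emp / (1.0 - p_emp))
        for i in range(S):
            for g in (0, 1):
                sel = (prep.study_idx == i) & (prep.group_idx == g)
                gci, zi = gc[sel], z[sel]
                if gci.size >= 2 and np.ptp(gci) > 0:
                    slope, intercept = np.polyfit(gci, zi, 1)
                    if slope < -0.05:
                        sigma = -1.0 / slope
                        E[i, g] = intercept * sigma
                        E[i, 2 + g] = math.log(min(max(sigma, 0.05), 20.0))
                        continue
                E[i, g] = gci.mean() + zi.mean()
                E[i, 2 + g] = 0.0
        theta = np.zeros(self.n_theta)
        theta[:4] = E.mean(axis=0)
        tau = np.clip(E.std(axis=0), 0.1, 2.0)
        rho = np.zeros(len(self.rho_keys))
        # chain-specific jitter for overdispersed starts
        E = E + 0.2 * rng.standard_normal(E.shape)
        theta[:4] += 0.2 * rng.standard_normal(4)
        if self.transform.estimated:
            lam0 = float(np.clip(lam0 + 0.1 * rng.standard_normal(),
                                 self.transform.prior_low + 1e-3,
                                 self.transform.prior_high - 1e-3))
        st = ChainState(effects=E, theta=theta, tau=tau, rho=rho, lam=lam0)
        if self.fixed_effects:
            st.tau = np.zeros(4)
            st.effects = self.mean_matrix(st.theta)
        return st

    # -- update blocks ----------------------------------------------------

    def update_effects(self, st: ChainState, warmup: bool):
        prep, rng = self.prep, self.rng
        cov = self._cov(st)
        ll = loglik_per_study(prep, st.effects, st.lam)
        lre = self.re_logpdf(st, cov=cov)
        for k in range(4):
            prop = st.effects.copy()
            prop[:, k] = st.effects[:, k] + self.eff_scale[:, k] * rng.standard_normal(
                prep.n_studies
            )
            ll_p = loglik_per_study(prep, prop, st.lam)
            lre_p = self.re_logpdf(st, effects=prop, cov=cov)
            log_acc = (ll_p + lre_p) - (ll + lre)
            accept = np.log(rng.uniform(size=prep.n_studies)) < log_acc
            st.effects[accept, k] = prop[accept, k]
            ll = np.where(accept, ll_p, ll)
            lre = np.where(accept, lre_p, lre)
            if warmup:
                gamma = 1.0 / (1.0 + self._adapt_t) ** 0.6
                self.eff_scale[:, k] *= np.exp(gamma * (accept.astype(float) - 0.44))
                np.clip(self.eff_scale[:, k], 1e-3, 10.0, out=self.eff_scale[:, k])

    def update_theta_gibbs(self, st: ChainState):
        """Conjugate draw of (means, coefficients) given effects and covariance."""
        cov = self._cov(st)
        try:
            si = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            return
        W = self.W
        A = np.einsum("ikp,kl,ilq->pq", W, si, W)
        b = np.einsum("ikp,kl,il->p", W, si, st.effects)
        prec = A + np.eye(self.n_theta) / self.prior.mean_sd**2
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b)
        z = self.rng.standard_normal(self.n_theta)
        st.theta = mean + np.linalg.solve(L.T, z)

    def update_theta_slice(self, st: ChainState):
        """Fixed-effects mode: means/coefficients act directly on the likelihood."""
        for p in range(self.n_theta):
            def logf(v, p=p):
                th = st.theta.copy()
                th[p] = v
                E = self.mean_matrix(th)
                return loglik_total(self.prep, E, st.lam) - 0.5 * (v / self.prior.mean_sd) ** 2
            st.theta[p], _ = slice_sample(
                st.theta[p], logf, -np.inf, np.inf, 1.0, self.rng
            )
        st.effects = self.mean_matrix(st.theta)

    def update_tau(self, st: ChainState):
        rng = self.rng
        upper = self.prior.tau_upper
        for k in range(4):
            # centered: tau_k | effects, means
            def logf_c(v, k=k):
                tau = st.tau.copy()
                tau[k] = v
                st2 = ChainState(st.effects, st.theta, tau, st.rho, st.lam)
                return float(self.re_logpdf(st2).sum())
            st.tau[k], _ = slice_sample(st.tau[k], logf_c, _TAU_FLOOR, upper,
                                        0.5 * max(st.tau[k], 0.1), rng)
        # interweaved non-centered step: keep standardised residuals fixed
        M = self.mean_matrix(st.theta)
        hp0 = bs.HyperParams(rho=dict(zip(self.rho_keys, st.rho)),
                             tau_mu1=1, tau_mu2=1, tau_sigma1=1, tau_sigma2=1)
        LR = np.linalg.cholesky(bs.correlation_matrix(hp0, self.structure) + 1e-12 * np.eye(4))
        # effects = M + (D LR u)^T  with D = diag(tau)
        resid = (st.effects - M) / st.tau  # rows: studies
        try:
            u = np.linalg.solve(LR, resid.T)  # (4, S)
        except np.linalg.LinAlgError:
            return
        for k in range(4):
            def logf_nc(v, k=k):
                tau = st.tau.copy()
                tau[k] = v
                E = M + (tau[:, None] * (LR @ u)).T
                return loglik_total(self.prep, E, st.lam)
            st.tau[k], _ = slice_sample(st.tau[k], logf_nc, _TAU_FLOOR, upper,
                                        0.5 * max(st.tau[k], 0.1), rng)
        st.effects = M + (st.tau[:, None] * (LR @ u)).T

    def update_rho(self, st: ChainState):
        lo, hi = self.prior.rho_bounds
        lo, hi = max(lo, -0.999), min(hi, 0.999)
        for k in range(len(self.rho_keys)):
            def logf(v, k=k):
                rho = st.rho.copy()
                rho[k] = v
                st2 = ChainState(st.effects, st.theta, st.tau, rho, st.lam)
                return float(self.re_logpdf(st2).sum())
            st.rho[k], _ = slice_sample(st.rho[k], logf, lo, hi, 0.3, self.rng)

    def update_lambda(self, st: ChainState, warmup: bool):
        lo, hi = self.transform.prior_low, self.transform.prior_high
        def logf(v):
            return loglik_total(self.prep, st.effects, v)
        st.lam, _ = slice_sample(st.lam, logf, lo, hi, 0.2, self.rng)
        for _ in range(3):
            self._lambda_rescale_move(st, warmup)

    # -- joint lambda move ------------------------------------------------

    def _ab(self, lam: float):
        """Affine reference frame of the transformed threshold scale.

        Frame scale/offset are the SD and mean of the transformed observed
        thresholds, so holding frame coordinates fixed while lambda moves
        keeps the implied rate curves aligned with the data in a
        least-squares sense across the whole threshold ladder.
        """
        logc = np.log(self._distinct_thresholds)
        g = logc if abs(lam) < 1e-8 else np.expm1(lam * logc) / lam
        return float(g.std()), float(g.mean())  # scale A, offset B

    def _log_posterior(self, st: ChainState) -> float:
        lp = loglik_total(self.prep, st.effects, st.lam)
        if not self.fixed_effects:
            lp += float(self.re_logpdf(st).sum())
            if np.any(st.tau <= 0) or np.any(st.tau >= self.prior.tau_upper):
                return -np.inf
        lp += -0.5 * float(np.sum((st.theta / self.prior.mean_sd) ** 2))
        if self.transform.estimated and not (
            self.transform.prior_low < st.lam < self.transform.prior_high
        ):
            return -np.inf
        return lp

    def _lambda_rescale_move(self, st: ChainState, warmup: bool):
        """Metropolis move of lambda with compensating affine transport.

        Location-type parameters are expressed in the frame anchored at the
        extreme observed thresholds; moving lambda while holding the frame
        coordinates fixed leaves the fitted rate curves nearly invariant,
        so the move travels along the posterior ridge.
        """
        if self.c_hi <= self.c_lo:
            return
        rng = self.rng
        lam_new = st.lam + self.lam_scale * rng.standard_normal()
        if not (self.transform.prior_low < lam_new < self.transform.prior_high):
            return
        A0, B0 = self._ab(st.lam)
        A1, B1 = self._ab(lam_new)
        a, loga = A1 / A0, math.log(A1 / A0)
        new = ChainState(st.effects.copy(), st.theta.copy(), st.tau.copy(),
                         st.rho.copy(), lam_new)
        new.effects[:, :2] = B1 + a * (st.effects[:, :2] - B0)
        new.effects[:, 2:] = st.effects[:, 2:] + loga
        new.theta = st.theta.copy()
        new.theta[:2] = B1 + a * (st.theta[:2] - B0)
        new.theta[2:4] = st.theta[2:4] + loga
        n_mu_coef = 0
        for r, sl in self.coef_slices.items():
            if r in (1, 2):
                new.theta[sl] = a * st.theta[sl]
                n_mu_coef += sl.stop - sl.start
        new.tau[:2] = a * st.tau[:2]
        S = self.prep.n_studies
        # transported location-type coordinates: study-level mus, m_mu1/2,
        # tau_mu1/2 (hierarchical mode only) and mu-targeted coefficients
        n_loc = 2 + n_mu_coef + (0 if self.fixed_effects else 2 * S + 2)
        log_jac = n_loc * loga
        if self.fixed_effects:
            new.effects = self.mean_matrix(new.theta)
        log_acc = self._log_posterior(new) - self._log_posterior(st) + log_jac
        accepted = math.log(rng.uniform()) < log_acc
        if accepted:
            st.effects, st.theta, st.tau, st.rho, st.lam = (
                new.effects, new.theta, new.tau, new.rho, new.lam)
        if warmup:
            gamma = 1.0 / (1.0 + self._adapt_t) ** 0.6
            self.lam_scale *= math.exp(gamma * (float(accepted) - 0.3))
            self.lam_scale = float(np.clip(self.lam_scale, 1e-3, 2.0))

    # -- main loop ---------------------------------------------------------

    def run(self, warmup: int, iterations: int, record):
        st = self.initial_state()
        for it in range(warmup + iterations):
            in_warmup = it < warmup
            self._adapt_t = it + 1
            if self.fixed_effects:
                self.update_theta_slice(st)
            else:
                self.update_effects(st, in_warmup)
                self.update_theta_gibbs(st)
                self.update_tau(st)
                if self.rho_keys:
                    self.update_rho(st)
            if self.transform.estimated:
                self.update_lambda(st, in_warmup)
            if not in_warmup:
                record(it - warmup, st)
        return st


# empirical marginals used by initialisation — attach to Prepared lazily
def _succ_marginal(self):
    # marginal count above each row's threshold (successes of the chain are
    # already the marginal counts; trials of later rows are previous counts)
    return self.succ


def _n_marginal(self):
    out = np.empty_like(self.trials)
    # N of the (study, group) run: trials of its first row
    current = 0.0
    for i in range(self.trials.size):
        if self.first[i]:
            current = self.trials[i]
        out[i] = current
    return out


Prepared.succ_marginal = property(_succ_marginal)
Prepared.n_marginal = property(_n_marginal)
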