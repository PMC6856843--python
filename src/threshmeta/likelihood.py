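"""Within-study model: positive-test probabilities and the multinomial
likelihood in its binomial factorisation.

Transformed test results g(y) in population j of study i are assumed
Logistic(mu_ij, sigma_ij), so the probability of a result above threshold
C is

    logit(pr_ijt) = (mu_ij - g(C_it)) / sigma_ij.

The spread of one group's N results across the T+1 intervals cut by its
thresholds is multinomial; it is fitted through the equivalent chain of
conditional binomials

    x_1 ~ Binomial(N, pr_1),  x_t | x_{t-1} ~ Binomial(x_{t-1}, pr_t / pr_{t-1}),

whose probability parameters are unconstrained in (0,1) — the monotonicity
of the fitted rates in threshold is automatic, no ordering constraints are
ever needed.  A direct multinomial evaluation is kept as an independent
test oracle.  All log-likelihoods include their combinatorial constants,
so the two routes agree exactly, not merely up to a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, xlogy

from .study_data import MetaDataset, ThresholdCounts, conditional_counts
from .transform import boxcox_vec

#: probabilities are clipped this far from {0, 1} before any log —
#: guards against underflow at extreme thresholds.
_P_CLIP = 1e-12


@dataclass(frozen=True)
class StudyEffects:
    """Location/scale of the transformed test-result distributions in one study."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("logistic scale parameters must be positive")


@dataclass(frozen=True)
class RateSet:
    """False/true positive rates aligned to one study's threshold grids."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self):
        for name, seq in (("fpr", self.fpr), ("tpr", self.tpr)):
            seq = np.asarray(seq, dtype=float)
            object.__setattr__(self, name, seq)
            if np.any((seq <= 0) | (seq >= 1)):
                raise ValueError(f"{name} values must lie strictly inside (0,1)")
            if np.any(np.diff(seq) >= 0):
                raise ValueError(f"{name} must be strictly decreasing in threshold")


def positive_rate(mu, sigma, g_c):
    """Probability of a test result above a threshold with transform value g_c.

    Inverse-logit of (mu - g_c)/sigma; strictly decreasing in g_c.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    out = expit((np.asarray(mu, float) - np.asarray(g_c, float)) / sigma)
    return out if out.ndim else float(out)


def _clip(p):
    return np.clip(p, _P_CLIP, 1.0 - _P_CLIP)


def _marginal_rates(tc: ThresholdCounts, mu, sigma, lam):
    g_c = boxcox_vec(tc.thresholds, lam)
    return _clip(positive_rate(mu, sigma, g_c))


def loglik_factorized(tc: ThresholdCounts, mu, sigma, lam) -> float:
    """Log-likelihood of one study-group via the conditional binomial chain."""
    pr = _marginal_rates(tc, mu, sigma, lam)
    cond_p = np.concatenate(([pr[0]], _clip(pr[1:] / pr[:-1])))
    pairs = np.asarray(conditional_counts(tc))
    trials, succ = pairs[:, 0], pairs[:, 1]
    return float(np.sum(stats.binom.logpmf(succ, trials, cond_p)))


def loglik_multinomial_oracle(tc: ThresholdCounts, mu, sigma, lam) -> float:
    """Direct multinomial log-likelihood of the same data (test oracle).

    Cell probabilities are (1-pr_1, pr_1-pr_2, ..., pr_T) and cell counts
    (N-x_1, x_1-x_2, ..., x_T).
    """
    pr = _marginal_rates(tc, mu, sigma, lam)
    cell_p = np.concatenate(([1.0 - pr[0]], -np.diff(pr), [pr[-1]]))
    x = tc.counts_above
    cell_x = np.concatenate(([tc.n - x[0]], -np.diff(x), [x[-1]]))
    return float(stats.multinomial.logpmf(cell_x, tc.n, cell_p / cell_p.sum()))


def deviance_terms(trials, successes, p_hat):
    """Residual deviance contributions of conditional binomial observations.

    2 * [x log(x/(n p)) + (n-x) log((n-x)/(n - n p))], with the usual
    0 log 0 := 0 conventions; zero-trial terms contribute nothing.
    """
    n = np.asarray(trials, dtype=float)
    x = np.asarray(successes, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fitted probabilities must lie strictly inside (0,1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(x, x) - xlogy(x, n * p) + xlogy(n - x, n - x) - xlogy(n - x, n - n * p)
    return 2.0 * np.where(n > 0, term, 0.0)


def conditional_probabilities(rates: np.ndarray) -> np.ndarray:
    """Marginal positive rates -> conditional binomial probabilities."""
    rates = np.asarray(rates, dtype=float)
    return np.concatenate(([rates[0]], _clip(rates[1:] / rates[:-1])))


def residual_deviance(dataset: MetaDataset, fitted_rates: dict) -> float:
    """Total residual deviance of fitted rates against a dataset.

    Parameters
    ----------
    dataset : MetaDataset
    fitted_rates : mapping study_id -> RateSet
        Marginal fpr/tpr aligned to each group's threshold grid; they are
        converted to the conditional probabilities of the binomial chain
        before the deviance is accumulated, matching the factorised
        sampling statement of the model.
    """
    total = 0.0
    for rec in dataset.records:
        rs = fitted_rates[rec.study_id]
        marginal = rs.fpr if rec.group == 1 else rs.tpr
        if len(marginal) != rec.n_thresholds:
            raise ValueError(
                f"study {rec.study_id!r}: fitted rates misaligned with data"
            )
        cond_p = conditional_probabilities(marginal)
        pairs = np.asarray(conditional_counts(rec))
        total += float(np.sum(deviance_terms(pairs[:, 0], pairs[:, 1], cond_p)))
    return total
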