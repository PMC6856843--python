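"""Post-fit summaries: accuracy curves across thresholds, SROC curve,
optimal-threshold selection and covariate effect ratios.

The summary false/true positive rate at threshold C evaluates the
within-study link at the means of the four sets of random effects:

    logit fpr(C) = (m_mu1 - g(C)) / exp(m_sigma1)
    logit tpr(C) = (m_mu2 - g(C)) / exp(m_sigma2)

per posterior draw (using that draw's lambda when the Box-Cox parameter is
estimated).  The headline point estimate is the posterior median of the
curve, which is transformation-equivariant; the curve evaluated at the
posterior means of the hyperparameters is also provided.  Prediction
intervals for a new study population are obtained by drawing one new set
of random effects per posterior draw from the fitted between-study law
(respecting the correlation structure) and evaluating the same link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import between_study as bs
from .inference import FitResult
from .transform import boxcox_vec

_HYP_COLS = ("m_mu1", "m_mu2", "m_sigma1", "m_sigma2")


@dataclass
class AccuracyCurve:
    """Summary accuracy across a threshold grid, with 95% CrI and PI bands."""

    thresholds: np.ndarray
    fpr_summary: np.ndarray
    tpr_summary: np.ndarray
    fpr_cri: np.ndarray  # (2, G) lower/upper
    tpr_cri: np.ndarray
    fpr_pi: np.ndarray | None = None
    tpr_pi: np.ndarray | None = None
    fpr_at_mean: np.ndarray | None = None  # curve at posterior-mean hyperparams
    tpr_at_mean: np.ndarray | None = None
    extrapolated: np.ndarray | None = None  # grid points outside the data range

    def to_frame(self) -> pd.DataFrame:
        data = {
            "threshold": self.thresholds,
            "fpr": self.fpr_summary,
            "tpr": self.tpr_summary,
            "fpr_lo": self.fpr_cri[0],
            "fpr_hi": self.fpr_cri[1],
            "tpr_lo": self.tpr_cri[0],
            "tpr_hi": self.tpr_cri[1],
        }
        if self.fpr_pi is not None:
            data.update(fpr_pi_lo=self.fpr_pi[0], fpr_pi_hi=self.fpr_pi[1],
                        tpr_pi_lo=self.tpr_pi[0], tpr_pi_hi=self.tpr_pi[1])
        if self.extrapolated is not None:
            data["extrapolated"] = self.extrapolated
        return pd.DataFrame(data)


def default_grid(fit: FitResult, n: int = 200) -> np.ndarray:
    """Log-spaced grid of n points spanning the observed threshold range."""
    thr = fit.prepared.thresholds
    return np.geomspace(thr.min(), thr.max(), n)


def _curve_draws(fit: FitResult, grid: np.ndarray):
    """(D, G) fpr and tpr draws of the summary curve."""
    grid = np.asarray(grid, dtype=float)
    lam = fit.lambda_draws()
    if np.any(grid <= 0) and np.any(lam <= 0):
        raise ValueError("non-positive thresholds are outside the transform domain")
    h = {k: fit.stacked(k)[:, None] for k in _HYP_COLS}
    logc = np.log(grid)[None, :]
    lam_col = lam[:, None]
    small = np.abs(lam_col) < 1e-8
    with np.errstate(over="ignore"):
        gc = np.where(small, logc,
                      np.expm1(np.where(small, 1.0, lam_col) * logc)
                      / np.where(small, 1.0, lam_col))
    fpr = expit((h["m_mu1"] - gc) / np.exp(h["m_sigma1"]))
    tpr = expit((h["m_mu2"] - gc) / np.exp(h["m_sigma2"]))
    return fpr, tpr


def summary_curve_closed_form(hp: bs.HyperParams, grid) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form summary fpr/tpr at fixed hyperparameter values."""
    grid = np.asarray(grid, dtype=float)
    gc = boxcox_vec(grid, hp.lam or 0.0)
    fpr = expit((hp.m_mu1 - gc) / np.exp(hp.m_sigma1))
    tpr = expit((hp.m_mu2 - gc) / np.exp(hp.m_sigma2))
    return fpr, tpr


def _flag_extrapolation(fit: FitResult, grid: np.ndarray, guard: float) -> np.ndarray:
    if fit.prepared is None:
        return np.zeros(grid.size, dtype=bool)
    thr = fit.prepared.thresholds
    lo, hi = thr.min() / (1 + guard), thr.max() * (1 + guard)
    out = (grid < lo) | (grid > hi)
    if out.any():
        warnings.warn(
            "summary grid extends beyond the observed threshold range; "
            "estimates at extreme thresholds rest on extrapolation"
        )
    return out


def summary_curve(fit: FitResult, grid=None, level: float = 0.95,
                  extrapolation_guard: float = 0.0) -> AccuracyCurve:
    """Posterior summary accuracy curve over a threshold grid."""
    grid = default_grid(fit) if grid is None else np.asarray(grid, dtype=float)
    fpr, tpr = _curve_draws(fit, grid)
    a = (1.0 - level) / 2.0
    qs = [a, 0.5, 1.0 - a]
    fq = np.quantile(fpr, qs, axis=0)
    tq = np.quantile(tpr, qs, axis=0)
    hp_mean = bs.HyperParams(
        **{k: float(fit.stacked(k).mean()) for k in _HYP_COLS},
        lam=float(fit.lambda_draws().mean()),
    )
    f_mean, t_mean = summary_curve_closed_form(hp_mean, grid)
    return AccuracyCurve(
        thresholds=grid,
        fpr_summary=fq[1], tpr_summary=tq[1],
        fpr_cri=fq[[0, 2]], tpr_cri=tq[[0, 2]],
        fpr_at_mean=f_mean, tpr_at_mean=t_mean,
        extrapolated=_flag_extrapolation(fit, grid, extrapolation_guard),
    )


def prediction_curve(fit: FitResult, grid=None, seed: int = 0,
                     level: float = 0.95) -> AccuracyCurve:
    """Summary curve augmented with prediction intervals for a new study.

    For each posterior draw, one new study's (mu*, log sigma*) is drawn
    from that draw's between-study law under the fitted correlation
    structure; the PI is the central interval of the resulting rates.
    """
    curve = summary_curve(fit, grid)
    grid = curve.thresholds
    rng = np.random.default_rng(seed)
    lam = fit.lambda_draws()
    D = lam.size
    h = {k: fit.stacked(k) for k in _HYP_COLS}
    taus = {k: fit.stacked(k) for k in
            ("tau_mu1", "tau_mu2", "tau_sigma1", "tau_sigma2")}
    rhos = {k.removeprefix("rho_"): fit.stacked(k)
            for k in fit.draws if k.startswith("rho_")}
    new_effects = np.empty((D, 4))
    for d in range(D):
        hp = bs.HyperParams(
            m_mu1=h["m_mu1"][d], m_mu2=h["m_mu2"][d],
            m_sigma1=h["m_sigma1"][d], m_sigma2=h["m_sigma2"][d],
            tau_mu1=taus["tau_mu1"][d], tau_mu2=taus["tau_mu2"][d],
            tau_sigma1=taus["tau_sigma1"][d], tau_sigma2=taus["tau_sigma2"][d],
            rho={k: float(v[d]) for k, v in rhos.items()},
        )
        new_effects[d] = bs.sample_effects_matrix(hp, fit.model.structure, 1, rng)[0]
    logc = np.log(grid)[None, :]
    lam_col = lam[:, None]
    small = np.abs(lam_col) < 1e-8
    gc = np.where(small, logc, np.expm1(np.where(small, 1.0, lam_col) * logc)
                  / np.where(small, 1.0, lam_col))
    fpr = expit((new_effects[:, [0]] - gc) / np.exp(new_effects[:, [2]]))
    tpr = expit((new_effects[:, [1]] - gc) / np.exp(new_effects[:, [3]]))
    a = (1.0 - level) / 2.0
    curve.fpr_pi = np.quantile(fpr, [a, 1.0 - a], axis=0)
    curve.tpr_pi = np.quantile(tpr, [a, 1.0 - a], axis=0)
    return curve


def sroc_curve(fit: FitResult, grid=None) -> np.ndarray:
    """Summary ROC curve: (fpr, tpr) pairs traced by varying the threshold.

    Pairs are ordered by threshold, so both coordinates decrease along the
    output.
    """
    curve = summary_curve(fit, grid)
    return np.column_stack([curve.fpr_summary, curve.tpr_summary])


def youden_optimal(curve: AccuracyCurve, sens_weight: float = 0.5) -> dict:
    """Optimal threshold by the (optionally weighted) Youden index.

    J_w = 2 (w * tpr + (1-w) * (1-fpr)) - 1; w = 0.5 reduces to the
    classical Youden index J = tpr - fpr.  Ties resolve to the smallest
    threshold.
    """
    if not 0.0 <= sens_weight <= 1.0:
        raise ValueError("sens_weight must lie in [0, 1]")
    tpr, fpr = curve.tpr_summary, curve.fpr_summary
    j = 2.0 * (sens_weight * tpr + (1.0 - sens_weight) * (1.0 - fpr)) - 1.0
    k = int(np.argmax(j))  # argmax returns the first (smallest C) maximiser
    return {
        "C_opt": float(curve.thresholds[k]),
        "sens": float(tpr[k]),
        "spec": float(1.0 - fpr[k]),
        "youden": float(j[k]),
    }


def covariate_ratio(fit: FitResult, covariate: str, delta: float, group: int) -> dict:
    """Multiplicative effect of a covariate change on the mean test result.

    On the log scale (lambda = 0), a coefficient alpha on mu_ij means a
    covariate increase of ``delta`` multiplies the (geometric) mean test
    result in group j by exp(delta * alpha).  This interpretation is
    specific to the log transform, so any other fixed or estimated lambda
    raises.
    """
    tr = fit.model.transform
    if tr.estimated or tr.lambda_value != 0.0:
        raise ValueError(
            "ratio interpretation of covariate effects requires the log "
            "transform (fixed lambda = 0): exp(delta * alpha) is a ratio of "
            "means only on the log scale"
        )
    if group not in (1, 2):
        raise ValueError("group must be 1 (disease-free) or 2 (diseased)")
    name = f"alpha{group}_{covariate}"
    if name not in fit.draws:
        raise KeyError(f"no fitted coefficient for covariate {covariate!r} on mu_i{group}")
    ratio = np.exp(delta * fit.stacked(name))
    lo, med, hi = np.quantile(ratio, [0.025, 0.5, 0.975])
    return {"ratio": float(med), "cri": (float(lo), float(hi))}
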