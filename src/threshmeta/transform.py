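"""Box-Cox transformation of the threshold scale.

The model assumes that some monotone transform g() of the raw test results
follows a logistic distribution in each population.  g() is restricted to
the Box-Cox family

    g(C) = (C^lambda - 1) / lambda   (lambda != 0)
    g(C) = log(C)                    (lambda == 0)

lambda = 1 corresponds to symmetric logistic test results (identity up to a
shift), lambda = 0 to log-logistic; decreasing lambda means increasing
right skew.  lambda may be fixed a priori or estimated from the data under
a uniform prior.

Thresholds must be strictly positive; zero or negative thresholds are
rejected rather than shifted (any shift constant is the caller's
preprocessing responsibility).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: below this |lambda| the log branch is used; expm1 keeps the power branch
#: numerically continuous down to this point.
_LOG_BRANCH_TOL = 1e-8


@dataclass
class TransformSpec:
    """Configuration of g(): fixed lambda, or estimated under Uniform(low, high).

    The default estimation prior is Uniform(-3, 3); a Uniform(1, 10) prior
    (used in earlier ROC-estimation work) can be requested for sensitivity
    analysis via ``prior_low``/``prior_high``.
    """

    mode: str = "fixed"  # "fixed" | "estimated"
    lambda_value: float = 0.0
    prior_low: float = -3.0
    prior_high: float = 3.0

    def __post_init__(self):
        if self.mode not in ("fixed", "estimated"):
            raise ValueError(f"unknown transform mode {self.mode!r}")
        if not self.prior_low < self.prior_high:
            raise ValueError("transform prior bounds must satisfy low < high")

    @property
    def estimated(self) -> bool:
        return self.mode == "estimated"


def boxcox(c, lam: float):
    """Box-Cox transform of positive threshold(s) ``c``.

    Strictly increasing in ``c`` for every ``lam`` and continuous in
    ``lam`` across 0 (the power branch is evaluated as
    ``expm1(lam * log c) / lam``, which degrades gracefully to the log
    branch as ``lam -> 0``).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("Box-Cox transform requires strictly positive thresholds")
    if abs(lam) < _LOG_BRANCH_TOL:
        out = np.log(c)
    elif abs(lam) < 1e-4:
        # expm1 avoids the cancellation in (C^lam - 1) for tiny lam
        out = np.expm1(lam * np.log(c)) / lam
    else:
        out = (c**lam - 1.0) / lam
    return out if out.ndim else float(out)


def boxcox_vec(thresholds, lam: float) -> np.ndarray:
    """Elementwise Box-Cox transform; preserves strict ordering."""
    return np.atleast_1d(boxcox(np.asarray(thresholds, dtype=float), lam))


def boxcox_inverse(g, lam: float):
    """Map transformed values back to the natural test-result scale.

    For ``lam != 0`` the inverse ``(lam * g + 1)^(1/lam)`` only exists when
    ``lam * g + 1 > 0``; values outside that domain raise.
    """
    g = np.asarray(g, dtype=float)
    if abs(lam) < _LOG_BRANCH_TOL:
        out = np.exp(g)
    else:
        base = lam * g + 1.0
        if np.any(base <= 0):
            raise ValueError("Box-Cox inverse undefined: lambda*g + 1 <= 0")
        out = base ** (1.0 / lam)
    return out if out.ndim else float(out)
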