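"""Estimation and confirmatory testing for a single-test diagnostic accuracy study.

Sensitivity and specificity are co-primary endpoints: the global null
hypothesis ``H0: se <= se0 or sp <= sp0`` is rejected only if both endpoint
nulls are rejected (intersection-union test).  Each endpoint test rejects
when the lower limit of a two-sided Wilson score confidence interval lies
strictly above the corresponding minimum value, so a two-sided level of
``1 - alpha`` per endpoint yields one-sided endpoint tests at ``alpha/2``
and, for stochastically independent endpoints, a global test at
``(alpha/2)**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "Counts2x2",
    "AccuracyEstimate",
    "ConfidenceInterval",
    "HypothesisPair",
    "IUTestResult",
    "EstimationUndefinedError",
    "estimate_accuracy",
    "wilson_bounds",
    "wilson_ci",
    "iu_test",
    "nominal_global_level",
    "se_of_proportion",
]


class EstimationUndefinedError(ValueError):
    """Raised when an accuracy estimate or interval is undefined (empty margin)."""


@dataclass(frozen=True)
class Counts2x2:
    """Agreement counts between the index test and the reference standard.

    Cases (target condition present) split into true positives and false
    negatives; controls split into true negatives and false positives.
    """

    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_fp", "n_tn", "n_fn"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @property
    def n_cases(self) -> int:
        return self.n_tp + self.n_fn

    @property
    def n_controls(self) -> int:
        return self.n_tn + self.n_fp

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class AccuracyEstimate:
    """Maximum-likelihood point estimates of sensitivity and specificity."""

    se_hat: float
    sp_hat: float


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(
                f"interval limits must satisfy 0 <= lower <= upper <= 1, "
                f"got ({self.lower}, {self.upper})"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class HypothesisPair:
    """Minimum acceptable sensitivity and specificity (se0, sp0)."""

    se0: float
    sp0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.se0 < 1.0 and 0.0 < self.sp0 < 1.0):
            raise ValueError(
                f"minimum values must lie in (0, 1), got ({self.se0}, {self.sp0})"
            )


@dataclass(frozen=True)
class IUTestResult:
    """Outcome of the intersection-union test on both endpoints."""

    reject_se: bool
    reject_sp: bool
    reject_global: bool
    estimate: AccuracyEstimate
    ci_se: ConfidenceInterval
    ci_sp: ConfidenceInterval


def estimate_accuracy(counts: Counts2x2) -> AccuracyEstimate:
    """Point estimates ``se_hat = TP/(TP+FN)`` and ``sp_hat = TN/(TN+FP)``."""
    if counts.n_cases == 0:
        raise EstimationUndefinedError(
            "sensitivity is undefined: zero cases (n_tp + n_fn = 0)"
        )
    if counts.n_controls == 0:
        raise EstimationUndefinedError(
            "specificity is undefined: zero controls (n_tn + n_fp = 0)"
        )
    return AccuracyEstimate(
        se_hat=counts.n_tp / counts.n_cases,
        sp_hat=counts.n_tn / counts.n_controls,
    )


def wilson_bounds(successes, n, level: float = 0.95):
    """Vectorized Wilson score interval for binomial proportions.

    Parameters may be scalars or arrays (broadcast together).  Returns
    ``(lower, upper)`` arrays clipped to [0, 1].  This closed form is the
    plain score interval without continuity correction.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    z = norm.ppf(0.5 + level / 2.0)
    k = np.asarray(successes, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise EstimationUndefinedError("Wilson interval undefined for n < 1")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("successes must satisfy 0 <= successes <= n")
    phat = k / n
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (phat + z2 / (2.0 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1.0 - phat) / n + z2 / (4.0 * n * n))
    lower = np.clip(center - half, 0.0, 1.0)
    upper = np.clip(center + half, 0.0, 1.0)
    # the closed form collapses exactly at the boundaries (center == half);
    # snap away the floating-point residue
    lower = np.where(k == 0, 0.0, lower)
    upper = np.where(k == n, 1.0, upper)
    return lower, upper


def wilson_ci(successes: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Two-sided Wilson score interval for ``successes`` out of ``n``."""
    if n == 0:
        raise EstimationUndefinedError("Wilson interval undefined for n = 0")
    lower, upper = wilson_bounds(successes, n, level)
    return ConfidenceInterval(lower=float(lower), upper=float(upper), level=level)


def iu_test(
    counts: Counts2x2, hyp: HypothesisPair, level: float = 0.95
) -> IUTestResult:
    """Intersection-union test of ``H0: se <= se0 or sp <= sp0``.

    Each endpoint null is rejected when the Wilson lower limit lies strictly
    above the minimum value; ties do not reject.  The global null is rejected
    only when both endpoint nulls are.
    """
    est = estimate_accuracy(counts)
    ci_se = wilson_ci(counts.n_tp, counts.n_cases, level)
    ci_sp = wilson_ci(counts.n_tn, counts.n_controls, level)
    reject_se = ci_se.lower > hyp.se0
    reject_sp = ci_sp.lower > hyp.sp0
    return IUTestResult(
        reject_se=reject_se,
        reject_sp=reject_sp,
        reject_global=reject_se and reject_sp,
        estimate=est,
        ci_se=ci_se,
        ci_sp=ci_sp,
    )


def nominal_global_level(alpha_one_sided: float) -> float:
    """Nominal level of the global test from the one-sided per-endpoint level.

    With independent endpoint tests each at one-sided level ``alpha``, the
    intersection-union test rejects the global null with probability at most
    ``alpha**2`` on its boundary (e.g. 0.025 per endpoint gives 0.000625).
    """
    if not 0.0 <= alpha_one_sided < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha_one_sided}")
    return alpha_one_sided**2


def se_of_proportion(p_true: float, n: int) -> float:
    """Binomial standard error ``sqrt(p (1 - p) / n)`` of a proportion estimate."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p_true <= 1.0:
        raise ValueError(f"p_true must be in [0, 1], got {p_true}")
    return math.sqrt(p_true * (1.0 - p_true) / n)
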