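"""Paired t-test over per-phase classifier accuracies.

Given two classifiers' accuracy series across the stages of a pipeline,
the test works on the absolute paired differences J_k = |a_k - b_k|:

    mu    = mean(J)
    sigma = sample standard deviation of J (divisor I - 1)
    T     = sqrt(I) * mu / sigma

with I experiments and df = I - 1 degrees of freedom.  The decision
compares |T| against the two-sided Student-t critical value at the
chosen alpha; |T| beyond the critical interval flags a significant
accuracy gap between the two series.

Note that using |differences| departs from the classic signed paired
t-test: mu can only be >= 0, so the procedure measures the magnitude of
the per-phase accuracy gap rather than its direction.  A ``literal``
variant of the statistic (I * mu / sigma instead of sqrt(I) * mu /
sigma) is available for transparency but is not the default, as only
the sqrt(I) form is a t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedAccuracySeries",
    "TTestResult",
    "paired_abs_differences",
    "paired_t_statistic",
    "t_decision",
    "run_paired_test",
]


@dataclass
class PairedAccuracySeries:
    """Two equal-length accuracy-percentage series to compare."""

    name_a: str
    name_b: str
    acc_a: np.ndarray
    acc_b: np.ndarray

    def __post_init__(self) -> None:
        self.acc_a = np.asarray(self.acc_a, dtype=float)
        self.acc_b = np.asarray(self.acc_b, dtype=float)
        if self.acc_a.shape != self.acc_b.shape:
            raise ValueError("accuracy series must have equal length")
        if self.acc_a.ndim != 1 or len(self.acc_a) < 2:
            raise ValueError("need 1-D series of length >= 2")


@dataclass
class TTestResult:
    J: np.ndarray
    mu: float
    sigma: float
    I: int
    T: float
    df: int
    degenerate: bool = False      # sigma == 0; T defined as 0
    alpha: float | None = None
    critical: float | None = None
    significant: bool | None = None
    literal_statistic: float | None = field(default=None)


def paired_abs_differences(series: PairedAccuracySeries) -> np.ndarray:
    """Elementwise absolute differences J = |a - b|."""
    return np.abs(series.acc_a - series.acc_b)


def paired_t_statistic(J, literal: bool = False) -> TTestResult:
    """Compute mu, sigma (sample sd, divisor I-1) and T = sqrt(I)*mu/sigma.

    ``literal=True`` reports I*mu/sigma as the main statistic instead.
    sigma == 0 (all differences equal) yields T = 0 with a degenerate flag.
    """
    J = np.asarray(J, dtype=float)
    I = len(J)
    if I < 2:
        raise ValueError("need at least two paired differences")
    mu = float(np.mean(J))
    sigma = float(np.std(J, ddof=1))
    degenerate = sigma == 0.0
    if degenerate:
        t_val, lit = 0.0, 0.0
    else:
        t_val = np.sqrt(I) * mu / sigma
        lit = I * mu / sigma
    main = lit if literal else t_val
    return TTestResult(J=J, mu=mu, sigma=sigma, I=I, T=float(main),
                       df=I - 1, degenerate=degenerate,
                       literal_statistic=float(lit))


def t_decision(result: TTestResult, alpha: float = 0.05) -> TTestResult:
    """Complete the result with the two-sided critical value and decision."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if result.df < 1:
        raise ValueError("df must be >= 1")
    result.alpha = alpha
    result.critical = float(stats.t.ppf(1.0 - alpha / 2.0, result.df))
    result.significant = bool(abs(result.T) > result.critical)
    return result


def run_paired_test(series: PairedAccuracySeries, alpha: float = 0.05,
                    literal: bool = False) -> TTestResult:
    """Convenience wrapper: differences -> statistic -> decision."""
    return t_decision(paired_t_statistic(paired_abs_differences(series),
                                         literal=literal), alpha)
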