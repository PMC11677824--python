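"""Welch's unequal-variance t comparison and normal-critical-value intervals.

Groups are summarised as (mean, variance, n).  The t statistic uses the
standard Welch form t = (m1 − m2)/sqrt(v1/n1 + v2/n2) with the
Welch–Satterthwaite fractional degrees of freedom, used unrounded in the
Student t distribution for the two-tailed p-value.  Confidence intervals
follow the reporting convention mean ± c·S/sqrt(n) with c the two-sided
standard-normal critical value (1.96 at alpha = 0.05); a t-based interval is
available behind a flag.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "welch_t",
    "welch_df",
    "p_two_tailed",
    "confidence_interval",
    "compare",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one measured group: mean, sample variance, n."""

    mean: float
    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group needs n >= 2")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    @classmethod
    def from_sample(cls, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(float(values.mean()), float(values.var(ddof=1)), int(values.size))


@dataclass(frozen=True)
class ComparisonResult:
    t: float
    df: float
    p_two_tailed: float
    significant: bool
    alpha: float = 0.05


def _check(a: GroupSummary, b: GroupSummary) -> None:
    if a.variance == 0 and b.variance == 0:
        raise ValueError("both variances are zero; t statistic undefined")


def welch_t(a: GroupSummary, b: GroupSummary) -> float:
    """Welch t statistic (m_a − m_b)/sqrt(v_a/n_a + v_b/n_b)."""
    _check(a, b)
    return (a.mean - b.mean) / np.sqrt(a.variance / a.n + b.variance / b.n)


def welch_df(a: GroupSummary, b: GroupSummary) -> float:
    """Welch–Satterthwaite degrees of freedom; fractional, not rounded."""
    _check(a, b)
    va, vb = a.variance / a.n, b.variance / b.n
    return (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))


def p_two_tailed(t: float, df: float) -> float:
    """Two-tailed p-value 2·P(T_df >= |t|) under Student's t (fractional df allowed)."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(2.0 * _st.t.sf(np.abs(t), df))


def confidence_interval(
    mean: float,
    S: float,
    n: int,
    alpha: float = 0.05,
    use_t: bool = False,
) -> tuple[float, float]:
    """Interval mean ± c·S/sqrt(n).

    By default c is the two-sided standard-normal critical value at ``alpha``
    (1.96 at 0.05, the conventional reporting constant even at modest n);
    ``use_t=True`` substitutes the Student t critical value with n − 1 df.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if S < 0:
        raise ValueError("standard deviation must be non-negative")
    if use_t:
        c = float(_st.t.ppf(1 - alpha / 2, n - 1))
    else:
        c = float(_st.norm.ppf(1 - alpha / 2))
    half = c * S / np.sqrt(n)
    return (mean - half, mean + half)


def compare(a: GroupSummary, b: GroupSummary, alpha: float = 0.05) -> ComparisonResult:
    """Full Welch comparison of two group summaries."""
    t = welch_t(a, b)
    df = welch_df(a, b)
    p = p_two_tailed(t, df)
    return ComparisonResult(t=float(t), df=float(df), p_two_tailed=p,
                            significant=bool(p < alpha), alpha=alpha)
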