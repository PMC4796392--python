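"""Variance and significance machinery for differences of two measured quantities.

Covers independent and paired/correlated measurements, symmetric and
asymmetric error bars, and binary proportions.  The central identity is

    var(A - B) = sigma_A^2 + sigma_B^2 - 2 r sigma_A sigma_B

which every routine here either evaluates directly or inherits through the
paired-sample plug-in estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AsymmetricInterval",
    "BinaryCounts",
    "BinarySplitResult",
    "PairedStats",
    "TTestResult",
    "binary_diff_variance",
    "binary_split_test",
    "classify_overlap",
    "combine_asymmetric_correlated",
    "combine_asymmetric_independent",
    "paired_difference_stats",
    "two_sample_t",
    "variance_of_difference",
]

DIFFERENT = "different"
NOT_DIFFERENT = "not_different"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class AsymmetricInterval:
    """Point estimate with distinct lower/upper half-widths.

    The interval is ``[estimate - lower, estimate + upper]`` at confidence
    ``level``.  ``warnings`` records any convention fallbacks (relabelling,
    radicand clipping) applied while constructing the interval.
    """

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.lower < 0 or self.upper < 0:
            raise ValueError("half-widths must be nonnegative")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")

    @property
    def low(self) -> float:
        return self.estimate - self.lower

    @property
    def high(self) -> float:
        return self.estimate + self.upper

    @classmethod
    def symmetric(cls, estimate: float, halfwidth: float, level: float = 0.95) -> "AsymmetricInterval":
        return cls(estimate, halfwidth, halfwidth, level)

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass(frozen=True)
class BinaryCounts:
    """Yes/no counts of a two-category classification."""

    n_yes: int
    n_no: int

    def __post_init__(self) -> None:
        if self.n_yes < 0 or self.n_no < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_yes + self.n_no


class PairedStats(NamedTuple):
    mean_diff: float
    var_diff: float
    se_diff: float
    n: int


class TTestResult(NamedTuple):
    statistic: float
    df: float


class BinarySplitResult(NamedTuple):
    delta_sq: float       # (n_yes - n_no)^2
    threshold: float      # z^2 * n  (4n for the ~95% rule)
    significant: bool


def _as_vector(x: Sequence[float], name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {arr.size}")
    return arr


def variance_of_difference(var_a: float, var_b: float, r: float) -> float:
    """Variance of A - B given the component variances and their correlation.

    Always lies within the envelope ``[(sd_a - sd_b)^2, (sd_a + sd_b)^2]``.
    """
    if var_a < 0 or var_b < 0:
        raise ValueError("variances must be nonnegative")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    return var_a + var_b - 2.0 * r * math.sqrt(var_a * var_b)


def paired_difference_stats(a: Sequence[float], b: Sequence[float]) -> PairedStats:
    """Mean, variance and standard error of the per-item differences a - b.

    Uses the unbiased (n-1) variance of the elementwise differences, which
    is algebraically identical to :func:`variance_of_difference` evaluated
    at the plug-in sample moments of ``a`` and ``b``.
    """
    av = _as_vector(a, "a", min_n=2)
    bv = _as_vector(b, "b", min_n=2)
    if av.size != bv.size:
        raise ValueError(f"length mismatch: {av.size} vs {bv.size}")
    d = av - bv
    n = d.size
    var_diff = float(np.var(d, ddof=1))
    return PairedStats(float(d.mean()), var_diff, math.sqrt(var_diff / n), n)


def _welch_satterthwaite_df(var_a: float, n_a: int, var_b: float, n_b: int) -> float:
    num = (var_a / n_a + var_b / n_b) ** 2
    den = (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
    if den == 0.0:
        return float(n_a + n_b - 2)
    return num / den


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_variance: bool = True
) -> TTestResult:
    """Two-sample t statistic and its degrees of freedom.

    ``equal_variance=True`` pools the two sample variances (df =
    n_a + n_b - 2); ``False`` uses the unpooled denominator with
    Welch-Satterthwaite degrees of freedom.  A zero-variance configuration
    with unequal means is signalled as an infinite statistic.
    """
    av = _as_vector(a, "a", min_n=2)
    bv = _as_vector(b, "b", min_n=2)
    n_a, n_b = av.size, bv.size
    var_a = float(np.var(av, ddof=1))
    var_b = float(np.var(bv, ddof=1))
    diff = float(av.mean() - bv.mean())
    if equal_variance:
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        se = math.sqrt((1.0 / n_a + 1.0 / n_b) * pooled)
        df = float(n_a + n_b - 2)
    else:
        se = math.sqrt(var_a / n_a + var_b / n_b)
        df = _welch_satterthwaite_df(var_a, n_a, var_b, n_b)
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df)
        return TTestResult(math.copysign(math.inf, diff), df)
    return TTestResult(diff / se, df)


def _check_levels(a: AsymmetricInterval, b: AsymmetricInterval) -> None:
    if not math.isclose(a.level, b.level, rel_tol=0, abs_tol=1e-12):
        raise ValueError(f"confidence levels differ: {a.level} vs {b.level}")


def combine_asymmetric_independent(
    a: AsymmetricInterval, b: AsymmetricInterval
) -> AsymmetricInterval:
    """Interval for the difference a - b of two independent asymmetric bars.

    The lower half of ``a`` combines in quadrature with the upper half of
    ``b`` (and vice versa).  By convention ``a`` is the larger estimate; if
    not, the operands are relabelled internally and the returned interval
    (still for a - b) carries a ``relabelled`` warning.
    """
    return combine_asymmetric_correlated(a, b, 0.0)


def combine_asymmetric_correlated(
    a: AsymmetricInterval, b: AsymmetricInterval, corr: float
) -> AsymmetricInterval:
    """Interval for a - b when the two estimates co-vary with correlation ``corr``.

    L = sqrt(L_A^2 + U_B^2 - 2 corr L_A U_B), U likewise with the roles
    swapped.  ``corr = 0`` reduces exactly to the independent combination.
    A negative radicand (possible for corr near 1 with unequal widths) is
    clipped at zero and flagged.
    """
    _check_levels(a, b)
    if not -1.0 <= corr <= 1.0:
        raise ValueError("corr must lie in [-1, 1]")
    warnings: list[str] = []
    if a.estimate < b.estimate:
        warnings.append("relabelled: a had the smaller estimate")
    rad_l = a.lower**2 + b.upper**2 - 2.0 * corr * a.lower * b.upper
    rad_u = b.lower**2 + a.upper**2 - 2.0 * corr * b.lower * a.upper
    if rad_l < 0 or rad_u < 0:
        warnings.append("radicand clipped at 0")
    lower = math.sqrt(max(rad_l, 0.0))
    upper = math.sqrt(max(rad_u, 0.0))
    return AsymmetricInterval(
        a.estimate - b.estimate, lower, upper, a.level, tuple(warnings)
    )


def binary_diff_variance(p_a: float, p_b: float, r: float) -> float:
    """Variance of the difference of two Bernoulli proportions.

    Complementary two-category case (p_a + p_b = 1, r = -1) collapses to
    4 * p_a (1 - p_a).
    """
    if not 0.0 <= p_a <= 1.0 or not 0.0 <= p_b <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return variance_of_difference(p_a * (1 - p_a), p_b * (1 - p_b), r)


def binary_split_test(c: BinaryCounts, level: float = 0.95) -> BinarySplitResult:
    """Is a yes/no split significantly different from 50:50?

    At the default ~95% level this is the 2/sqrt(N) rule: significant iff
    (n_yes - n_no)^2 > 4 N.  Other levels substitute the squared Gaussian
    critical value for the factor 4.
    """
    if c.n == 0:
        raise ValueError("empty counts")
    delta_sq = float((c.n_yes - c.n_no) ** 2)
    if math.isclose(level, 0.95, abs_tol=1e-12):
        factor = 4.0  # the z ~ 2 convention behind the printed rule
    else:
        factor = stats.norm.ppf(0.5 + level / 2.0) ** 2
    threshold = factor * c.n
    return BinarySplitResult(delta_sq, threshold, delta_sq > threshold)


def classify_overlap(
    a: AsymmetricInterval, b: AsymmetricInterval, dependent: bool = False
) -> str:
    """Verdict on whether two error-barred estimates differ.

    Independent measures: different iff the composite quadrature interval
    for the difference excludes zero (overlap of the individual bars is NOT
    the test).  Dependent measures: non-overlapping bars are different; one
    bar nested inside the other cannot be different regardless of the
    correlation; anything else is indeterminate without knowing it.
    """
    _check_levels(a, b)
    if not dependent:
        comp = combine_asymmetric_independent(a, b)
        return DIFFERENT if not comp.contains(0.0) else NOT_DIFFERENT
    # dependent: interval geometry only
    if a.high < b.low or b.high < a.low:
        return DIFFERENT
    a_inside_b = b.low <= a.low and a.high <= b.high
    b_inside_a = a.low <= b.low and b.high <= a.high
    if a_inside_b or b_inside_a:
        return NOT_DIFFERENT
    return INDETERMINATE


def flip(interval: AsymmetricInterval) -> AsymmetricInterval:
    """The interval for the negated quantity."""
    return replace(
        interval,
        estimate=-interval.estimate,
        lower=interval.upper,
        upper=interval.lower,
    )
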