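"""Family-wise comparison of many methods.

Family-wise error arithmetic, Holm-Bonferroni (step-down) and Hochberg
(step-up) procedures, paired chi-squared tests over categories, one-way
ANOVA with its nested-model F reading, adjusted r^2, covariance whitening
and the correlated chi-squared statistic, Tukey HSD, and the
equivalence-grouping layout for depicting many methods at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "CovarianceModel",
    "GroupingLayout",
    "PValueFamily",
    "PerformanceMatrix",
    "StepwiseResult",
    "TukeyResult",
    "adjusted_r2",
    "anova_oneway",
    "chi2_two_methods",
    "chi2_vs_expected",
    "correlated_chi2",
    "f_test_nested",
    "fwer",
    "grouping_layout",
    "hochberg_step_up",
    "holm_bonferroni",
    "studentized_range_quantile",
    "tukey_hsd",
    "whiten",
]

EIGENVALUE_FLOOR_RATIO = 1e-10


@dataclass(frozen=True)
class PValueFamily:
    """A family of per-method p-values tested against one reference method."""

    labels: tuple[str, ...]
    p_values: tuple[float, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "p_values", tuple(float(p) for p in self.p_values))
        if len(self.labels) != len(self.p_values):
            raise ValueError("labels and p_values must have the same length")
        if any(not 0.0 <= p <= 1.0 for p in self.p_values):
            raise ValueError("p-values must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PerformanceMatrix:
    """M methods x N systems grid of a scalar metric (complete, no gaps)."""

    methods: tuple[str, ...]
    systems: tuple[str, ...]
    values: np.ndarray  # shape (M, N)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "systems", tuple(self.systems))
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (methods x systems)")
        if v.shape != (len(self.methods), len(self.systems)):
            raise ValueError("shape mismatch between labels and values")
        if np.isnan(v).any():
            raise ValueError("matrix must be complete (no missing cells)")
        if len(self.methods) < 2 or len(self.systems) < 2:
            raise ValueError("need at least 2 methods and 2 systems")

    @property
    def n_methods(self) -> int:
        return len(self.methods)

    @property
    def n_systems(self) -> int:
        return len(self.systems)

    def method_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def method_variances(self) -> np.ndarray:
        return self.values.var(axis=1, ddof=1)


class StepwiseResult(NamedTuple):
    significant: dict[str, bool]
    order: tuple[str, ...]          # ascending-p visit order (stable on ties)
    thresholds: tuple[float, ...]   # alpha / (N + 1 - k) in that order


@dataclass(frozen=True)
class AnovaResult:
    ss_global: float
    ss_local: float
    ss_total: float
    df_global: int
    df_local: int
    df_total: int
    f_statistic: float
    p_value: float
    critical: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.f_statistic > self.critical


@dataclass(frozen=True)
class CovarianceModel:
    """Eigendecomposition-backed whitener for a method covariance matrix."""

    covariance: np.ndarray          # V, M x M
    eigenvalues: np.ndarray         # lambda^2, after flooring
    rotation: np.ndarray            # A, columns are eigenvectors
    whitener: np.ndarray            # W = A diag(1/lambda) A^T
    floored: tuple[int, ...] = ()   # indices of floored eigenvalues


class Chi2Result(NamedTuple):
    statistic: float
    df: int
    p_value: float


class TukeyResult(NamedTuple):
    labels: tuple[str, ...]
    statistics: np.ndarray          # M x M, |mean_i - mean_j| / pooled SE
    critical: float                 # studentized-range quantile q(M, M(N-1))
    significant: np.ndarray         # boolean M x M
    pooled_se: float


@dataclass(frozen=True)
class GroupingLayout:
    """Column layout of methods by statistical equivalence.

    Each column is a set of mutually indistinguishable methods, ordered
    best to worst top to bottom; columns are ordered left to right by their
    best member.  Cross-column pairs that are nevertheless not
    significantly different are recorded as dotted edges.
    """

    columns: tuple[tuple[str, ...], ...]
    edges: tuple[tuple[str, str], ...]
    means: dict[str, float]
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)


def fwer(p: float, k: int) -> float:
    """Family-wise error probability of >= 1 false positive in k tests at level p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - p) ** k


def _sorted_family(f: PValueFamily) -> list[tuple[float, str]]:
    # stable sort: ties broken by input order, which itself is label order
    return sorted(zip(f.p_values, f.labels), key=lambda t: t[0])


def holm_bonferroni(f: PValueFamily) -> StepwiseResult:
    """Step-down Holm-Bonferroni procedure.

    Visit p-values ascending; the k-th is tested against alpha/(N+1-k)
    with a strict inequality.  The first failure stops the scan: that
    method and every larger-p method is declared non-significant.
    """
    ordered = _sorted_family(f)
    n = len(ordered)
    significant: dict[str, bool] = {}
    thresholds = []
    failed = False
    for k, (p, label) in enumerate(ordered, start=1):
        thr = f.alpha / (n + 1 - k)
        thresholds.append(thr)
        if not failed and p < thr:
            significant[label] = True
        else:
            failed = True
            significant[label] = False
    return StepwiseResult(
        significant, tuple(label for _, label in ordered), tuple(thresholds)
    )


def hochberg_step_up(f: PValueFamily) -> StepwiseResult:
    """Step-up Hochberg procedure.

    Scan from the largest p downwards; the first k with p_(k) <= alpha/(N+1-k)
    makes that method and every smaller-p method significant.  Rejects a
    superset of Holm's on any family.
    """
    ordered = _sorted_family(f)
    n = len(ordered)
    thresholds = [f.alpha / (n + 1 - k) for k in range(1, n + 1)]
    cut = 0
    for k in range(n, 0, -1):
        if ordered[k - 1][0] <= thresholds[k - 1]:
            cut = k
            break
    significant = {
        label: (k <= cut) for k, (_, label) in enumerate(ordered, start=1)
    }
    return StepwiseResult(
        significant, tuple(label for _, label in ordered), tuple(thresholds)
    )


def chi2_two_methods(
    counts_e: Sequence[int], counts_f: Sequence[int]
) -> Chi2Result:
    """Paired chi-squared over M categories for two methods.

    Each category's expected count is the two methods' average; requires
    equal totals (the methods classified the same examples).
    """
    e = np.asarray(counts_e, dtype=float)
    fv = np.asarray(counts_f, dtype=float)
    if e.shape != fv.shape or e.ndim != 1:
        raise ValueError("count vectors must be equal-length 1-D")
    if (e < 0).any() or (fv < 0).any():
        raise ValueError("counts must be nonnegative")
    if e.sum() != fv.sum():
        raise ValueError("totals must match for paired classification counts")
    expected = (e + fv) / 2.0
    if (expected == 0).any():
        raise ValueError("zero expected count in some category")
    stat = float((((e - expected) ** 2) / expected).sum())
    df = e.size - 1
    return Chi2Result(stat, df, float(stats.chi2.sf(stat, df)))


def chi2_vs_expected(
    counts_e: Sequence[int], counts_o: Sequence[float]
) -> Chi2Result:
    """Chi-squared of observed counts against externally known expected counts."""
    e = np.asarray(counts_e, dtype=float)
    o = np.asarray(counts_o, dtype=float)
    if e.shape != o.shape or e.ndim != 1:
        raise ValueError("count vectors must be equal-length 1-D")
    if (o <= 0).any():
        raise ValueError("expected counts must be positive")
    stat = float((((e - o) ** 2) / o).sum())
    df = e.size - 1
    return Chi2Result(stat, df, float(stats.chi2.sf(stat, df)))


def anova_oneway(
    pm: PerformanceMatrix | Sequence[Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA of method means over systems.

    Accepts a PerformanceMatrix or a sequence of per-method value groups
    (which may have unequal sizes; the between-group sum of squares then
    weights each group by its own n).
    """
    if isinstance(pm, PerformanceMatrix):
        groups = [pm.values[i] for i in range(pm.n_methods)]
    else:
        groups = [np.asarray(g, dtype=float) for g in pm]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_global = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_local = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ss_total = float(((all_values - grand) ** 2).sum())
    m = len(groups)
    n_total = all_values.size
    df_global = m - 1
    df_local = n_total - m
    df_total = n_total - 1
    if ss_local == 0.0:
        f_stat = math.inf if ss_global > 0 else 0.0
    else:
        f_stat = (ss_global / df_global) / (ss_local / df_local)
    return AnovaResult(
        ss_global=ss_global,
        ss_local=ss_local,
        ss_total=ss_total,
        df_global=df_global,
        df_local=df_local,
        df_total=df_total,
        f_statistic=f_stat,
        p_value=float(stats.f.sf(f_stat, df_global, df_local)) if math.isfinite(f_stat) else 0.0,
        critical=float(stats.f.ppf(1.0 - alpha, df_global, df_local)),
        alpha=alpha,
    )


def f_test_nested(
    ss_simple: float, df_simple: int, ss_complex: float, df_complex: int
) -> tuple[float, float]:
    """F test of a simpler (fewer-parameter) model against a nested richer one.

    F = ((ss_simple - ss_complex)/(df_simple - df_complex)) / (ss_complex/df_complex).
    Feeding ANOVA's total and local sums reproduces the one-way F exactly.
    """
    if df_simple <= df_complex:
        raise ValueError("simpler model must have more residual df")
    if df_complex < 1:
        raise ValueError("df underflow")
    if ss_simple < ss_complex:
        raise ValueError("nested model cannot fit worse than the richer one")
    num = (ss_simple - ss_complex) / (df_simple - df_complex)
    if ss_complex == 0.0:
        return (math.inf if num > 0 else 0.0, 0.0)
    f_stat = num / (ss_complex / df_complex)
    return f_stat, float(stats.f.sf(f_stat, df_simple - df_complex, df_complex))


def adjusted_r2(r2: float, p_params: int, n: int) -> float:
    """Parameter-penalised r^2: r^2 - (1 - r^2) p / (n - p - 1)."""
    if n - p_params - 1 <= 0:
        raise ValueError("need n - p - 1 > 0")
    return r2 - (1.0 - r2) * p_params / (n - p_params - 1)


def whiten(pm: PerformanceMatrix) -> CovarianceModel:
    """Whitening transform for the method-to-method covariance of a matrix.

    V is formed from system-wise deviations with the 1/(N-1) denominator,
    eigendecomposed as V = A diag(lambda^2) A^T, and the whitener is
    W = A diag(1/lambda) A^T so that W V W^T = I.  Near-zero eigenvalues
    (duplicated methods) are floored at EIGENVALUE_FLOOR_RATIO times the
    largest and recorded.
    """
    dev = pm.values - pm.values.mean(axis=1, keepdims=True)
    v = dev @ dev.T / (pm.n_systems - 1)
    return whiten_covariance(v)


def whiten_covariance(v: np.ndarray) -> CovarianceModel:
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(v)
    top = float(eigvals.max())
    if top <= 0.0:
        raise ValueError("all-zero covariance cannot be whitened")
    floor = EIGENVALUE_FLOOR_RATIO * top
    floored = tuple(int(i) for i in np.nonzero(eigvals < floor)[0])
    eigvals = np.maximum(eigvals, floor)
    w = eigvecs @ np.diag(1.0 / np.sqrt(eigvals)) @ eigvecs.T
    return CovarianceModel(
        covariance=v,
        eigenvalues=eigvals,
        rotation=eigvecs,
        whitener=w,
        floored=floored,
    )


def correlated_chi2(means: Sequence[float], v: np.ndarray) -> Chi2Result:
    """Chi-squared for equality of M method means with covariance V.

    The common mean is the generalised-least-squares value
    mu = (1' V^-1 1)^-1 1' V^-1 <x>, and the statistic is the whitened
    quadratic form (<x> - mu 1)' V^-1 (<x> - mu 1) with M - 1 df.  ``v``
    is the covariance of the mean estimates themselves.
    """
    x = np.asarray(means, dtype=float)
    model = whiten_covariance(np.asarray(v, dtype=float))
    w = model.whitener
    vinv = w.T @ w
    ones = np.ones_like(x)
    denom = float(ones @ vinv @ ones)
    mu = float(ones @ vinv @ x) / denom
    resid = x - mu
    stat = float(resid @ vinv @ resid)
    df = x.size - 1
    return Chi2Result(stat, df, float(stats.chi2.sf(stat, df)))


def studentized_range_quantile(level: float, n_groups: int, df: int) -> float:
    """Quantile of the studentized range distribution q(n_groups, df)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    return float(stats.studentized_range.ppf(level, n_groups, df))


def tukey_hsd(pm: PerformanceMatrix, level: float = 0.95) -> TukeyResult:
    """Tukey-style honest-significant-difference statistics for all pairs.

    t(i,j) = |mean_i - mean_j| / sqrt(sum_i var_i / (N M)) compared to the
    studentized-range quantile q(M, M(N-1)) at ``level``.  Verdicts are
    invariant under affine rescaling of the whole matrix.
    """
    means = pm.method_means()
    variances = pm.method_variances()
    pooled_se = math.sqrt(variances.sum() / (pm.n_systems * pm.n_methods))
    if pooled_se == 0.0:
        raise ValueError("zero pooled variance")
    statistics = np.abs(means[:, None] - means[None, :]) / pooled_se
    critical = studentized_range_quantile(
        level, pm.n_methods, pm.n_methods * (pm.n_systems - 1)
    )
    significant = statistics > critical
    np.fill_diagonal(significant, False)
    return TukeyResult(pm.methods, statistics, critical, significant, pooled_se)


def grouping_layout(
    labels: Sequence[str],
    means: Sequence[float],
    significant: np.ndarray,
    intervals: dict[str, tuple[float, float]] | None = None,
) -> GroupingLayout:
    """Column layout of methods by pairwise statistical equivalence.

    ``significant[i, j]`` is True when methods i and j are statistically
    different.  Methods are ordered by mean; consecutive runs in which all
    pairs are mutually non-significant form columns (grown from the worst
    end, which is the orientation that keeps the largest equivalence blocks
    intact).  Non-significant pairs that end up in different columns become
    dotted edges.
    """
    sig = np.asarray(significant, dtype=bool)
    m = len(labels)
    if sig.shape != (m, m):
        raise ValueError("significance matrix shape mismatch")
    if not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric")
    order = sorted(range(m), key=lambda i: (-means[i], labels[i]))
    # grow maximal all-pairs-equivalent groups from the worst method upward
    columns_rev: list[list[int]] = []
    for idx in reversed(order):
        placed = False
        if columns_rev:
            col = columns_rev[-1]
            if all(not sig[idx, j] for j in col):
                col.append(idx)
                placed = True
        if not placed:
            columns_rev.append([idx])
    columns = tuple(
        tuple(labels[i] for i in reversed(col)) for col in reversed(columns_rev)
    )
    col_of = {lab: ci for ci, col in enumerate(columns) for lab in col}
    edges = []
    for a_pos in range(m):
        for b_pos in range(a_pos + 1, m):
            i, j = order[a_pos], order[b_pos]
            if not sig[i, j] and col_of[labels[i]] != col_of[labels[j]]:
                edges.append((labels[i], labels[j]))
    return GroupingLayout(
        columns=columns,
        edges=tuple(edges),
        means={labels[i]: float(means[i]) for i in range(m)},
        intervals=intervals or {},
    )


def layout_from_matrix(pm: PerformanceMatrix, level: float = 0.95) -> GroupingLayout:
    """Convenience: Tukey HSD verdicts -> grouping layout."""
    res = tukey_hsd(pm, level)
    return grouping_layout(pm.methods, pm.method_means(), res.significant)
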