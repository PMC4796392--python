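"""AUC and ROC-enrichment statistics with correlation-aware error bars.

Both metrics are averages of binary outranking events, so their variances
reduce to Bernoulli arithmetic over per-active / per-inactive indicator
vectors, and the covariance between two methods scored on the same
compounds follows from the joint indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "AucDifference",
    "EnrichmentDifference",
    "EnrichmentResult",
    "IndicatorMatrix",
    "ScoreSet",
    "auc",
    "correlated_auc_difference",
    "correlated_enrichment_difference",
    "delong_variance",
    "enrichment_variance",
    "roc_enrichment",
    "roc_slope",
]

COV_DEFINITION = "definition"
COV_WORKED_EXAMPLE = "worked_example"


@dataclass(frozen=True)
class ScoreSet:
    """Scores of one method over a labelled compound set (higher = better rank)."""

    active_scores: tuple[float, ...]
    inactive_scores: tuple[float, ...]
    method_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "active_scores", tuple(float(s) for s in self.active_scores))
        object.__setattr__(self, "inactive_scores", tuple(float(s) for s in self.inactive_scores))
        if not self.active_scores or not self.inactive_scores:
            raise ValueError("need at least one active and one inactive")

    @property
    def n_active(self) -> int:
        return len(self.active_scores)

    @property
    def n_inactive(self) -> int:
        return len(self.inactive_scores)


@dataclass(frozen=True)
class IndicatorMatrix:
    """Active-vs-inactive outranking indicators chi_{i,j} in {0, 1/2, 1}.

    Row means are the per-active placement probabilities p_i; the grand
    mean is the AUC.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.size == 0:
            raise ValueError("indicator matrix must be 2-D and nonempty")
        object.__setattr__(self, "entries", e)

    @property
    def row_means(self) -> np.ndarray:
        return self.entries.mean(axis=1)

    @property
    def col_means(self) -> np.ndarray:
        return self.entries.mean(axis=0)


@dataclass(frozen=True)
class EnrichmentResult:
    """ROC enrichment at inactive-fraction f.

    ``f_used`` is the realised fraction ceil(f * N_inactive) / N_inactive,
    reported back because f need not divide the inactive count evenly.
    """

    f: float
    f_used: float
    g: float                       # fraction of actives above the threshold
    enrichment: float              # E = g / f
    slope: float                   # ROC slope approximation at f
    threshold: float               # score of the defining ranked inactive
    active_selected: np.ndarray = field(repr=False)
    inactive_selected: np.ndarray = field(repr=False)


class AucDifference(NamedTuple):
    diff: float
    se: float
    auc_a: float
    auc_b: float


class EnrichmentDifference(NamedTuple):
    diff: float
    se: float
    result_a: EnrichmentResult
    result_b: EnrichmentResult
    cov_active: float
    cov_inactive: float


def auc(s: ScoreSet) -> tuple[float, IndicatorMatrix]:
    """AUC as the mean outranking indicator over all (active, inactive) pairs.

    Ties are credited 1/2.  Returns the full indicator matrix alongside for
    the variance/covariance machinery.
    """
    act = np.asarray(s.active_scores)[:, None]
    inact = np.asarray(s.inactive_scores)[None, :]
    chi = np.where(act > inact, 1.0, np.where(act == inact, 0.5, 0.0))
    m = IndicatorMatrix(chi)
    return float(chi.mean()), m


def delong_variance(m: IndicatorMatrix) -> float:
    """Placement-component variance of the AUC.

    var = var(row means)/N_active + var(col means)/N_inactive with the
    unbiased (N-1) denominators.  A degenerate side with a single compound
    contributes 0; a 1x1 matrix has no variance information at all.
    """
    n_a, n_i = m.entries.shape
    if n_a == 1 and n_i == 1:
        raise ValueError("variance undefined for a single active and single inactive")
    var_active = float(np.var(m.row_means, ddof=1)) if n_a > 1 else 0.0
    var_inactive = float(np.var(m.col_means, ddof=1)) if n_i > 1 else 0.0
    return var_active / n_a + var_inactive / n_i


def _check_aligned(a: ScoreSet, b: ScoreSet) -> None:
    if a.n_active != b.n_active or a.n_inactive != b.n_inactive:
        raise ValueError("score sets must cover the same compounds in the same order")


def _indicator_cov(chi_a: np.ndarray, chi_b: np.ndarray, axis: int) -> float:
    """Covariance of per-compound placement probabilities of two methods.

    axis=1: per-active (mean over inactives of the joint indicator minus
    the product of row means, averaged with the N-1 denominator); axis=0:
    per-inactive, with the complementary indicators.
    """
    n = chi_a.shape[1 - axis]
    if n < 2:
        return 0.0
    joint = (chi_a * chi_b).mean(axis=axis)
    p_a = chi_a.mean(axis=axis)
    p_b = chi_b.mean(axis=axis)
    return float((joint - p_a * p_b).sum() / (n - 1))


def correlated_auc_difference(a: ScoreSet, b: ScoreSet) -> AucDifference:
    """Difference of two AUCs on the same compounds, with a correlation-aware SE.

    se^2 subtracts twice the per-active and per-inactive covariance terms
    from the sum of the two one-method (DeLong-style) variances.
    """
    _check_aligned(a, b)
    auc_a, m_a = auc(a)
    auc_b, m_b = auc(b)
    n_act, n_inact = m_a.entries.shape
    # complementary matrices: inactive outranking active
    comp_a = 1.0 - m_a.entries
    comp_b = 1.0 - m_b.entries

    def side_var(x: np.ndarray, axis: int) -> float:
        means = x.mean(axis=axis)
        return float(np.var(means, ddof=1)) if means.size > 1 else 0.0

    var_act = side_var(m_a.entries, 1) + side_var(m_b.entries, 1)
    cov_act = _indicator_cov(m_a.entries, m_b.entries, axis=1)
    var_inact = side_var(comp_a, 0) + side_var(comp_b, 0)
    cov_inact = _indicator_cov(comp_a, comp_b, axis=0)
    se2 = (var_act - 2.0 * cov_act) / n_act + (var_inact - 2.0 * cov_inact) / n_inact
    return AucDifference(auc_a - auc_b, math.sqrt(max(se2, 0.0)), auc_a, auc_b)


def roc_enrichment(s: ScoreSet, f: float) -> EnrichmentResult:
    """ROC enrichment at inactive-fraction f.

    The threshold is the score of the ceil(f * N_inactive)-th ranked
    inactive; an active is selected iff it scores strictly above it (ties
    at the threshold count as not selected).  E = g / f where g is the
    selected-active fraction.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    n_i = s.n_inactive
    k = math.ceil(f * n_i)
    if k < 1:
        raise ValueError("f * N_inactive must be at least 1")
    inact = np.asarray(s.inactive_scores)
    order = np.argsort(-inact, kind="stable")
    threshold = float(inact[order[k - 1]])
    inactive_selected = np.zeros(n_i, dtype=bool)
    inactive_selected[order[:k]] = True
    act = np.asarray(s.active_scores)
    active_selected = act > threshold
    g = float(active_selected.mean())
    e = g / f
    return EnrichmentResult(
        f=f,
        f_used=k / n_i,
        g=g,
        enrichment=e,
        slope=roc_slope(e, f),
        threshold=threshold,
        active_selected=active_selected,
        inactive_selected=inactive_selected,
    )


def roc_slope(e: float, f: float) -> float:
    """ROC-curve slope approximation at inactive-fraction f: E (1 + ln E / ln f).

    Returns 0 at E = 0 by continuity and clips negative values to 0.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    if e < 0:
        raise ValueError("enrichment must be nonnegative")
    if e == 0.0:
        return 0.0
    return max(e * (1.0 + math.log(e) / math.log(f)), 0.0)


def enrichment_variance(e: EnrichmentResult, n_active: int, n_inactive: int) -> float:
    """Variance of the probability-scaled enrichment E*f.

    Active term g(1-g)/N_active plus S^2 f(1-f)/N_inactive where S is the
    ROC slope at f.
    """
    g, f, s = e.g, e.f, e.slope
    return g * (1.0 - g) / n_active + s * s * f * (1.0 - f) / n_inactive


def _enrichment_cov(
    sel_a: np.ndarray, sel_b: np.ndarray, mode: str
) -> float:
    """Covariance of two selection-indicator vectors.

    ``definition``: mean joint indicator minus product of means (the only
    convention with cov = var for identical methods).  ``worked_example``:
    joint-selection fraction times the geometric mean of the two Bernoulli
    variances, which is the convention behind the known printed arithmetic.
    """
    a = np.asarray(sel_a, dtype=float)
    b = np.asarray(sel_b, dtype=float)
    g_a, g_b = a.mean(), b.mean()
    joint = float((a * b).mean())
    if mode == COV_DEFINITION:
        return joint - g_a * g_b
    if mode in (COV_WORKED_EXAMPLE, "worked-example"):
        return joint * math.sqrt(g_a * (1 - g_a) * g_b * (1 - g_b))
    raise ValueError("cov_mode must be 'definition' or 'worked_example'")


def correlated_enrichment_difference(
    a: ScoreSet, b: ScoreSet, f: float, cov_mode: str = COV_DEFINITION
) -> EnrichmentDifference:
    """Difference of two ROC enrichments on the same compounds, with SE.

    se^2 = (1/f^2) [ (v_act^A + v_act^B - 2 cov_act)/N_active
                     + (S_A^2 v_in^A + S_B^2 v_in^B - 2 S_A S_B cov_in)/N_inactive ]
    with the Bernoulli variances of the selection indicators and the
    covariance convention chosen by ``cov_mode``.
    """
    _check_aligned(a, b)
    ea = roc_enrichment(a, f)
    eb = roc_enrichment(b, f)
    n_act, n_inact = a.n_active, a.n_inactive
    v_act_a = ea.g * (1 - ea.g)
    v_act_b = eb.g * (1 - eb.g)
    fi_a = ea.f_used
    fi_b = eb.f_used
    v_in_a = fi_a * (1 - fi_a)
    v_in_b = fi_b * (1 - fi_b)
    cov_act = _enrichment_cov(ea.active_selected, eb.active_selected, cov_mode)
    cov_in = _enrichment_cov(ea.inactive_selected, eb.inactive_selected, cov_mode)
    se2 = (
        (v_act_a + v_act_b - 2.0 * cov_act) / n_act
        + (ea.slope**2 * v_in_a + eb.slope**2 * v_in_b - 2.0 * ea.slope * eb.slope * cov_in)
        / n_inact
    ) / f**2
    return EnrichmentDifference(
        ea.enrichment - eb.enrichment,
        math.sqrt(max(se2, 0.0)),
        ea,
        eb,
        cov_act,
        cov_in,
    )
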