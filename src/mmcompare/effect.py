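"""Size-of-effect and Bayesian reinterpretation utilities.

Standardised effect size, probability of superiority, the diagnostic-test
posterior (the antidote to the transposed-conditional fallacy), the
minimum Bayes odds-ratio recalibration of p-values, and a flat/tabulated
prior posterior over a true difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BayesOdds",
    "DiagnosticTest",
    "EffectSummary",
    "cohens_d",
    "cohens_d_from_summary",
    "minimum_bayes_odds",
    "posterior_difference_density",
    "posterior_positive",
    "prob_superiority",
]


@dataclass(frozen=True)
class DiagnosticTest:
    """Prevalence, sensitivity (power) and false-positive rate of a test."""

    prevalence: float
    power: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "power", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


class EffectSummary(NamedTuple):
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    d: float
    p_superiority: float


class BayesOdds(NamedTuple):
    odds: float
    posterior_null: float
    weak_regime: bool  # True when p >= 1/e, where the bound gives odds <= 1


def cohens_d_from_summary(
    mean_a: float,
    mean_b: float,
    sd_a: float,
    sd_b: float,
    pooling: str = "sum",
) -> float:
    """Standardised absolute mean difference.

    Default denominator is sqrt(sd_a^2 + sd_b^2) — the root of the *sum*
    of variances.  ``pooling="classic"`` uses the conventional pooled
    average sqrt((sd_a^2 + sd_b^2)/2) instead.
    """
    var_sum = sd_a**2 + sd_b**2
    if var_sum == 0.0:
        raise ValueError("variances cannot both be zero")
    if pooling == "sum":
        denom = math.sqrt(var_sum)
    elif pooling == "classic":
        denom = math.sqrt(var_sum / 2.0)
    else:
        raise ValueError("pooling must be 'sum' or 'classic'")
    return abs(mean_b - mean_a) / denom


def cohens_d(
    a: Sequence[float], b: Sequence[float], pooling: str = "sum"
) -> float:
    """Cohen's d from two samples, with (n-1)-denominator variances."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    return cohens_d_from_summary(
        float(av.mean()),
        float(bv.mean()),
        float(av.std(ddof=1)),
        float(bv.std(ddof=1)),
        pooling=pooling,
    )


def prob_superiority(d: float, mode: str = "linear") -> float:
    """Probability a random draw from the better method beats the other.

    ``linear``: the rule-of-thumb 0.25 d + 0.5 (intended for d in [0, 1];
    larger d raises a warning and the value is capped at 1).  ``exact``:
    Phi(d / sqrt(2)) for two equal-width Gaussians.
    """
    if d < 0:
        raise ValueError("d must be nonnegative (absolute effect size)")
    if mode == "linear":
        if d > 1.0:
            import warnings

            warnings.warn("linear approximation is only intended for d in [0, 1]")
        return min(0.25 * d + 0.5, 1.0)
    if mode == "exact":
        return float(stats.norm.cdf(d / math.sqrt(2.0)))
    raise ValueError("mode must be 'linear' or 'exact'")


def effect_summary(a: Sequence[float], b: Sequence[float]) -> EffectSummary:
    """Effect-size bundle for two samples (d plus exact superiority)."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    d = cohens_d(av, bv)
    return EffectSummary(
        float(av.mean()),
        float(bv.mean()),
        float(av.std(ddof=1)),
        float(bv.std(ddof=1)),
        d,
        prob_superiority(d, mode="exact"),
    )


def minimum_bayes_odds(p: float, prior_q: float | None = None) -> BayesOdds:
    """Best-case odds in favour of a real effect implied by a p-value.

    O = -1 / (e p ln p), optionally scaled by a prior odds factor q.  The
    closed form is only meaningful for p < 1/e; beyond that the bound drops
    to even odds or worse and ``weak_regime`` is set.  The posterior
    probability of the null is 1 / (1 + O).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    odds = -1.0 / (math.e * p * math.log(p))
    if prior_q is not None:
        if prior_q < 0:
            raise ValueError("prior odds factor must be nonnegative")
        odds *= prior_q
    return BayesOdds(odds, 1.0 / (1.0 + odds), p >= 1.0 / math.e)


def posterior_positive(dt: DiagnosticTest) -> float:
    """P(condition | positive test) by Bayes' rule."""
    num = dt.power * dt.prevalence
    denom = num + dt.alpha * (1.0 - dt.prevalence)
    if denom == 0.0:
        raise ValueError("degenerate test: zero probability of a positive result")
    return num / denom


def posterior_difference_density(
    observed_mean: float,
    se: float,
    grid: Sequence[float] | None = None,
    prior: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior density over the true difference given an observed mean.

    With a flat prior this is just the CLT Gaussian centred on the observed
    mean with standard deviation ``se``.  A tabulated ``prior`` (aligned
    with ``grid``) is multiplied in and the result renormalised over the
    grid.  Returns ``(grid, density)`` with the density normalised to unit
    mass under trapezoidal integration.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if grid is None:
        grid = np.linspace(observed_mean - 6 * se, observed_mean + 6 * se, 1201)
    g = np.asarray(grid, dtype=float)
    like = stats.norm.pdf(g, loc=observed_mean, scale=se)
    if prior is not None:
        pr = np.asarray(prior, dtype=float)
        if pr.shape != g.shape:
            raise ValueError("prior grid must align with the difference grid")
        if (pr < 0).any():
            raise ValueError("prior must be nonnegative")
        like = like * pr
    mass = float(np.trapezoid(like, g))
    if mass <= 0 or not math.isfinite(mass):
        raise ValueError("non-normalizable prior/likelihood product")
    return g, like / mass
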