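"""Synthetic data generators for every statistic in the package.

Includes the noise-model generator behind the correlation-of-correlations
simulations (two predictors of a common reference, with independent or
shared noise streams), binormal score-set pairs with a tunable inter-method
correlation, Gaussian performance matrices with prescribed method
covariance, and the small worked virtual-screening fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mmcompare.multi import PerformanceMatrix
from mmcompare.roc import ScoreSet

__all__ = [
    "NoiseModelConfig",
    "demo_screen_pair",
    "gen_correlated_predictors",
    "gen_performance_matrix",
    "gen_score_set",
    "replicate_correlations",
    "replicate_trivariate_correlations",
]


@dataclass(frozen=True)
class NoiseModelConfig:
    """Configuration of the two-predictor noise model.

    Predictors of a common reference x (n_points evenly spaced over
    x_range, endpoints inclusive):

        y_i = x_i + gamma * N(0,1)_y,i + eta     * N(0,1)_z,i
        z_i = x_i + delta * N(0,1)_y,i + epsilon * N(0,1)_z,i

    With ``shared_noise=False`` the cross amplitudes (eta for y, delta for
    z's share of y's stream) are forced to the independent layout: y uses
    only gamma, z uses only epsilon.  ``shared_noise=True`` lets z reuse
    y's noise stream with amplitude delta, which raises the inter-predictor
    correlation while leaving each marginal correlation with x untouched
    whenever delta^2 + epsilon^2 is held constant.
    """

    gamma: float = 0.595
    eta: float = 0.0
    delta: float = 0.925
    epsilon: float = 0.0
    n_points: int = 50
    x_range: tuple[float, float] = (0.0, 4.0)
    shared_noise: bool = False
    seed: int | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("gamma", "eta", "delta", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")


def gen_correlated_predictors(
    cfg: NoiseModelConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw replicate (x, y, z) triples under the noise model.

    Returns ``x`` of shape (n_points,) and ``y``, ``z`` of shape
    (replicates, n_points).  Deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.linspace(cfg.x_range[0], cfg.x_range[1], cfg.n_points)
    shape = (cfg.replicates, cfg.n_points)
    noise_y = rng.standard_normal(shape)
    noise_z = rng.standard_normal(shape)
    if cfg.shared_noise:
        y = x + cfg.gamma * noise_y + cfg.eta * noise_z
        z = x + cfg.delta * noise_y + cfg.epsilon * noise_z
    else:
        y = x + cfg.gamma * noise_y
        z = x + cfg.delta * noise_z
    return x, y, z


def replicate_correlations(
    cfg: NoiseModelConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-replicate (r_xy, r_xz, r_yz) under the noise model, vectorised."""
    x, y, z = gen_correlated_predictors(cfg)

    def corr_with_x(m: np.ndarray) -> np.ndarray:
        xc = x - x.mean()
        mc = m - m.mean(axis=1, keepdims=True)
        num = mc @ xc
        return num / (np.sqrt((mc**2).sum(axis=1)) * np.sqrt((xc**2).sum()))

    def corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        num = (ac * bc).sum(axis=1)
        return num / np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))

    return corr_with_x(y), corr_with_x(z), corr_rows(y, z)


def replicate_trivariate_correlations(
    r_xy: float,
    r_xz: float,
    r_yz: float,
    n: int,
    replicates: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-replicate sample correlations from a trivariate normal population.

    This is the sampling design behind the covariance-of-correlations
    approximation (all three variables random, x shared), unlike the
    fixed-x-grid noise model where the two sample correlations are
    independent across replicates by construction.
    """
    cov = np.array([[1.0, r_xy, r_xz], [r_xy, 1.0, r_yz], [r_xz, r_yz, 1.0]])
    chol = np.linalg.cholesky(cov)  # raises for an infeasible triplet
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((replicates, n, 3)) @ chol.T

    def corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        return (ac * bc).sum(axis=1) / np.sqrt(
            (ac**2).sum(axis=1) * (bc**2).sum(axis=1)
        )

    x, y, z = draws[..., 0], draws[..., 1], draws[..., 2]
    return corr_rows(x, y), corr_rows(x, z), corr_rows(y, z)


def gen_score_set(
    n_active: int,
    n_inactive: int,
    separation: float,
    correlation: float = 0.0,
    seed: int | None = None,
    separation_b: float | None = None,
) -> tuple[ScoreSet, ScoreSet]:
    """Paired binormal score sets with a tunable inter-method correlation.

    Actives score N(separation, 1), inactives N(0, 1); the correlation knob
    mixes a shared per-compound noise stream with method-private streams,
    so ``correlation=1`` yields identical scores (and zero SE for any
    paired difference).  ``separation_b`` lets the second method have its
    own active/inactive separation (defaults to the first).
    """
    if n_active < 1 or n_inactive < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 <= correlation <= 1.0:
        raise ValueError("correlation knob must lie in [0, 1]")
    if separation_b is None:
        separation_b = separation
    rng = np.random.default_rng(seed)
    n = n_active + n_inactive
    shared = rng.standard_normal(n)
    private_a = rng.standard_normal(n)
    private_b = rng.standard_normal(n)
    w_shared = np.sqrt(correlation)
    w_priv = np.sqrt(1.0 - correlation)
    noise_a = w_shared * shared + w_priv * private_a
    noise_b = w_shared * shared + w_priv * private_b
    signal_a = np.r_[np.full(n_active, separation), np.zeros(n_inactive)]
    signal_b = np.r_[np.full(n_active, separation_b), np.zeros(n_inactive)]
    scores_a = signal_a + noise_a
    scores_b = signal_b + noise_b
    set_a = ScoreSet(tuple(scores_a[:n_active]), tuple(scores_a[n_active:]), "A")
    set_b = ScoreSet(tuple(scores_b[:n_active]), tuple(scores_b[n_active:]), "B")
    return set_a, set_b


def gen_performance_matrix(
    n_methods: int,
    n_systems: int,
    means: np.ndarray | list[float],
    covariance: np.ndarray | list[list[float]],
    seed: int | None = None,
    method_labels: list[str] | None = None,
) -> PerformanceMatrix:
    """Gaussian performance matrix with prescribed method-to-method covariance.

    Each system is an independent draw of the M method scores from
    MVN(means, covariance).
    """
    mu = np.asarray(means, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    if mu.shape != (n_methods,):
        raise ValueError("means must have one entry per method")
    if cov.shape != (n_methods, n_methods):
        raise ValueError("covariance must be M x M")
    # SPD check via Cholesky
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(n_methods))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mu, cov, size=n_systems, method="cholesky")
    labels = method_labels or [f"M{i + 1}" for i in range(n_methods)]
    systems = [f"S{j + 1}" for j in range(n_systems)]
    return PerformanceMatrix(tuple(labels), tuple(systems), draws.T)


def demo_screen_pair() -> tuple[ScoreSet, ScoreSet]:
    """A small two-method virtual-screening fixture (8 actives, 10 inactives).

    Scores are constructed so that, at inactive-fraction 0.2, method A
    selects actives {1,2,3} and method B selects {1,2,5,6} (joint count 2),
    while the top-2 inactives are {1,2} for A and {1,3} for B (joint count
    1) — the marginals behind the worked enrichment-difference arithmetic.
    """
    # method A ranking (high to low): a1 a2 a3 | i1 i2 | a4..a8 i3..i10
    a_active = (18.0, 17.0, 16.0, 13.0, 12.5, 12.0, 11.5, 11.0)
    a_inactive = (15.0, 14.0, 10.0, 9.5, 9.0, 8.5, 8.0, 7.5, 7.0, 6.5)
    # method B ranking: a1 a2 a5 a6 | i1 i3 | a3 a4 a7 a8 i2 i4..i10
    b_active = (18.0, 17.0, 12.0, 11.5, 16.0, 15.5, 11.0, 10.5)
    b_inactive = (14.0, 9.0, 13.0, 8.5, 8.0, 7.5, 7.0, 6.5, 6.0, 5.5)
    return (
        ScoreSet(a_active, a_inactive, "A"),
        ScoreSet(b_active, b_inactive, "B"),
    )
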