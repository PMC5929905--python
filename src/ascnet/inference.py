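"""Monte-Carlo null-hypothesis tests for additive-signal-change classes.

The observed covariances of a node pair in two states are noisy; a change
in correlation can only be attributed (or denied) to a class of additive
signal change after accounting for that noise. The procedure:

1. Sample putative *true* state-A covariances and true state-B variances
   from inverse-Wishart posteriors around the observed summaries, at the
   effective degrees of freedom of the data (flat prior on the covariance,
   rejection of degenerate draws).
2. For each draw, find the member of the tested class that minimises and
   the member that maximises the true state-B correlation compatible with
   the drawn state-A covariance and state-B variances, then sample an
   *observed* state-B correlation from a Wishart distribution at the
   state-B degrees of freedom. This yields null distributions for the
   smallest and largest observable correlation under the class.
3. Reject the class if the observed state-B correlation falls below the
   lower quantile of the min-extreme distribution or above the upper
   quantile of the max-extreme distribution. The test is conservative:
   most class members produce smaller changes than the extremal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .bounds import (
    additive_bounds_batch,
    common_bounds_batch,
    uncorrelated_predicted_correlation,
)
from .covariance import StateCovariance, TwoStateSummary, correlation

__all__ = [
    "McConfig",
    "ClassTestResult",
    "CovarianceDraws",
    "sample_true_covariances",
    "null_distribution",
    "class_test",
    "correlation_change_test",
    "CLASS_IDS",
]

CLASS_IDS = ("uncorrelated", "common", "additive")

ClassId = Literal["uncorrelated", "common", "additive"]


@dataclass(frozen=True)
class McConfig:
    """Settings for the Monte-Carlo class tests."""

    n_iterations: int = 2000
    interval_level: float = 0.95
    seed: int = 0
    dof_override: float | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be at least 100")
        if not 0.0 < self.interval_level < 1.0:
            raise ValueError("interval_level must lie strictly inside (0, 1)")
        if self.dof_override is not None and self.dof_override <= 0:
            raise ValueError("dof_override must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass(frozen=True)
class ClassTestResult:
    """Outcome of one class test on one edge."""

    class_id: str
    null_lo_interval: tuple[float, float]
    null_hi_interval: tuple[float, float]
    observed_rho_b: float
    p_below: float
    p_above: float
    rejected: bool
    n_rejected_draws: int = 0


@dataclass(frozen=True)
class CovarianceDraws:
    """Posterior draws of true state-A covariances and state-B variances."""

    rho_a: np.ndarray
    var_ax: np.ndarray
    var_ay: np.ndarray
    var_bx: np.ndarray
    var_by: np.ndarray
    n_rejected: int = 0


def _dofs(summary: TwoStateSummary, cfg: McConfig) -> tuple[float, float]:
    if cfg.dof_override is not None:
        return cfg.dof_override, cfg.dof_override
    return summary.state_a.dof_eff, summary.state_b.dof_eff


def sample_true_covariances(summary: TwoStateSummary, cfg: McConfig) -> CovarianceDraws:
    """Draw putative true covariances consistent with the observed summaries.

    State-A 2x2 covariances come from ``InvWishart(df=dof_A, scale=dof_A*QA)``
    (flat prior on the covariance, Wishart likelihood at the effective dof);
    state-B variances from the matching one-dimensional marginals
    (inverse-gamma). Draws that are numerically non-positive-definite or
    degenerate are rejected and redrawn; a rejection rate above 99% raises.
    """
    dof_a, dof_b = _dofs(summary, cfg)
    if min(dof_a, dof_b) < 4:
        raise ValueError("effective dof must be at least 4 for covariance sampling")
    rng = cfg.rng(salt=1)
    n = cfg.n_iterations
    qa = summary.state_a.matrix

    out = dict(rho_a=[], var_ax=[], var_ay=[])
    n_rejected = 0
    need = n
    while need > 0:
        draw = stats.invwishart.rvs(df=dof_a, scale=dof_a * qa,
                                    size=need, random_state=rng)
        draw = np.atleast_3d(draw).reshape(-1, 2, 2)
        vx, vy, cxy = draw[:, 0, 0], draw[:, 1, 1], draw[:, 0, 1]
        det = vx * vy - cxy ** 2
        ok = (vx > 0) & (vy > 0) & (det > 1e-12 * vx * vy)
        n_rejected += int((~ok).sum())
        if n_rejected > 100 * n:
            raise RuntimeError(
                f"covariance rejection sampling failed: {n_rejected} rejected draws")
        out["rho_a"].append(cxy[ok] / np.sqrt(vx[ok] * vy[ok]))
        out["var_ax"].append(vx[ok])
        out["var_ay"].append(vy[ok])
        need = n - sum(len(v) for v in out["rho_a"])
    rho_a = np.concatenate(out["rho_a"])[:n]
    var_ax = np.concatenate(out["var_ax"])[:n]
    var_ay = np.concatenate(out["var_ay"])[:n]
    # state-B variance posteriors: one-dimensional inverse-Wishart marginals
    var_bx = stats.invgamma.rvs(a=dof_b / 2,
                                scale=dof_b * summary.state_b.var_x / 2,
                                size=n, random_state=rng)
    var_by = stats.invgamma.rvs(a=dof_b / 2,
                                scale=dof_b * summary.state_b.var_y / 2,
                                size=n, random_state=rng)
    return CovarianceDraws(rho_a=rho_a, var_ax=var_ax, var_ay=var_ay,
                           var_bx=var_bx, var_by=var_by, n_rejected=n_rejected)


def _observed_correlation(rho_true: np.ndarray, dof: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample observed correlations at the given true values via Wishart noise.

    Uses the Bartlett decomposition of a 2x2 Wishart with identity-free
    scale: for a bivariate Gaussian with correlation ``rho`` and n effective
    samples, the sample correlation can be generated from three independent
    variates (two chi, one normal).
    """
    n = rho_true.shape[0]
    df = max(float(dof), 3.0)
    rho_true = np.clip(rho_true, -1.0, 1.0)
    # Bartlett: W = L A A' L' with A = [[c11, 0], [z, c22]] and L the
    # Cholesky factor of [[1, rho], [rho, 1]] (rows (1, 0) and (rho, q))
    c11 = np.sqrt(rng.chisquare(df, size=n))
    c22 = np.sqrt(rng.chisquare(df - 1, size=n))
    z = rng.normal(size=n)
    q = np.sqrt(np.maximum(1.0 - rho_true ** 2, 0.0))
    w11 = c11 ** 2
    w12 = rho_true * w11 + q * c11 * z
    w22 = rho_true ** 2 * w11 + 2 * rho_true * q * c11 * z + q ** 2 * (z ** 2 + c22 ** 2)
    with np.errstate(invalid="ignore"):
        r = w12 / np.sqrt(w11 * w22)
    return np.clip(np.where(np.isfinite(r), r, rho_true), -1.0, 1.0)


def _class_extremes(class_id: str, draws: CovarianceDraws
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Extremal true state-B correlations per draw; NaN draws are dropped."""
    if class_id == "uncorrelated":
        point = draws.rho_a * np.sqrt(
            (draws.var_ax * draws.var_ay) / (draws.var_bx * draws.var_by))
        point = np.clip(point, -1.0, 1.0)
        return point, point, 0
    if class_id == "common":
        lo, hi = common_bounds_batch(draws.rho_a, draws.var_ax, draws.var_ay,
                                     draws.var_bx, draws.var_by)
    elif class_id == "additive":
        lo, hi = additive_bounds_batch(draws.rho_a, draws.var_ax, draws.var_ay,
                                       draws.var_bx, draws.var_by)
    else:
        raise ValueError(f"unknown class_id {class_id!r}")
    ok = np.isfinite(lo) & np.isfinite(hi)
    return lo[ok], hi[ok], int((~ok).sum())


def null_distribution(summary: TwoStateSummary, class_id: ClassId,
                      cfg: McConfig) -> tuple[np.ndarray, np.ndarray]:
    """Null distributions of the observed state-B correlation for one class.

    Returns ``(min_extreme, max_extreme)`` samples: for each posterior draw
    the class member minimising (maximising) the true state-B correlation
    is selected and an observed correlation is sampled at the state-B
    effective dof. For the uncorrelated class the two coincide up to
    observation noise.
    """
    draws = sample_true_covariances(summary, cfg)
    lo_true, hi_true, n_infeasible = _class_extremes(class_id, draws)
    if lo_true.size < max(10, cfg.n_iterations // 100):
        raise RuntimeError(
            f"class {class_id!r}: {n_infeasible} of {cfg.n_iterations} draws infeasible")
    _, dof_b = _dofs(summary, cfg)
    rng = cfg.rng(salt=2)
    lo_obs = _observed_correlation(lo_true, dof_b, rng)
    hi_obs = _observed_correlation(hi_true, dof_b, rng)
    return lo_obs, hi_obs


def _tail_quantiles(x: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])  # type-7 interpolation
    return float(lo), float(hi)


def class_test(summary: TwoStateSummary, class_id: ClassId,
               cfg: McConfig) -> ClassTestResult:
    """Test whether one ASC class can explain the observed two-state change.

    The class is rejected when the observed state-B correlation falls below
    the lower tail of the min-extreme null distribution or above the upper
    tail of the max-extreme distribution at ``cfg.interval_level``.
    P-values are smoothed empirical tail proportions ``(r + 1) / (n + 1)``.

    A class that is infeasible for (nearly) every posterior draw — e.g. a
    common signal cannot produce a strong variance decrease in one node
    and an increase in the other at high correlation — cannot explain the
    observation and is reported as rejected outright.
    """
    try:
        lo_obs, hi_obs = null_distribution(summary, class_id, cfg)
    except RuntimeError:
        return ClassTestResult(
            class_id=class_id,
            null_lo_interval=(np.nan, np.nan),
            null_hi_interval=(np.nan, np.nan),
            observed_rho_b=correlation(summary.state_b),
            p_below=0.0, p_above=0.0, rejected=True,
            n_rejected_draws=cfg.n_iterations,
        )
    observed = correlation(summary.state_b)
    n_lo, n_hi = lo_obs.size, hi_obs.size
    p_below = (np.sum(lo_obs <= observed) + 1) / (n_lo + 1)
    p_above = (np.sum(hi_obs >= observed) + 1) / (n_hi + 1)
    lo_iv = _tail_quantiles(lo_obs, cfg.interval_level)
    hi_iv = _tail_quantiles(hi_obs, cfg.interval_level)
    rejected = bool(observed < lo_iv[0] or observed > hi_iv[1])
    return ClassTestResult(
        class_id=class_id,
        null_lo_interval=lo_iv,
        null_hi_interval=hi_iv,
        observed_rho_b=observed,
        p_below=float(p_below),
        p_above=float(p_above),
        rejected=rejected,
    )


def correlation_change_test(summary: TwoStateSummary,
                            cfg: McConfig | None = None) -> float:
    """Two-sided p-value for a change in correlation between the states.

    Fisher z-transform of both correlations with standard error
    ``sqrt(1/(dof_A - 3) + 1/(dof_B - 3))`` at the states' effective
    degrees of freedom.
    """
    rho_a = correlation(summary.state_a)
    rho_b = correlation(summary.state_b)
    if abs(rho_a) >= 1.0 or abs(rho_b) >= 1.0:
        raise ValueError("degenerate correlation of magnitude 1")
    if cfg is not None and cfg.dof_override is not None:
        dof_a = dof_b = cfg.dof_override
    else:
        dof_a, dof_b = summary.state_a.dof_eff, summary.state_b.dof_eff
    if min(dof_a, dof_b) <= 3:
        raise ValueError("effective dof must exceed 3 for the Fisher z test")
    z = np.arctanh(rho_a) - np.arctanh(rho_b)
    se = np.sqrt(1.0 / (dof_a - 3.0) + 1.0 / (dof_b - 3.0))
    return float(2.0 * stats.norm.sf(abs(z) / se))
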