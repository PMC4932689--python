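"""Random-effects analysis of a multicenter trial on the risk-difference scale.

Each center contributes an estimated risk difference (treatment minus
standard) with its sampling variance; centers are pooled with the
DerSimonian-Laird method-of-moments estimator of the between-center variance
tau^2, so the pooled effect's uncertainty reflects any treatment-by-center
interaction. The pooled estimate is tested with a two-sided Wald normal test.

When a center has a zero or full cell, a continuity correction (0.5 added to
each of the four cells, i.e. 1 to each arm's total) keeps its weight finite;
the correction is applied per center, only where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trial import SimulatedTrial

__all__ = [
    "CenterEffect",
    "REAnalysisResult",
    "center_effect",
    "pool_random_effects",
    "significance_test",
    "analyze_trial",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class CenterEffect:
    """One center's estimated risk difference (treatment minus standard)."""

    rd: float
    var: float
    corrected: bool

    def __post_init__(self) -> None:
        if self.var <= 0.0:
            raise ValueError("center-effect variance must be positive")


@dataclass(frozen=True)
class REAnalysisResult:
    """Pooled random-effects result.

    ``mu`` is the pooled risk difference, ``nu`` its variance, ``tau2`` the
    estimated between-center variance of the effect, ``z``/``p_value`` the
    two-sided Wald normal test, and ``significant`` the 5%-level verdict.
    """

    mu: float
    nu: float
    tau2: float
    z: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "nu": self.nu,
            "tau2": self.tau2,
            "z": self.z,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def _center_effects(
    n_s: np.ndarray, y_s: np.ndarray, n_t: np.ndarray, y_t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-center risk differences and variances.

    Returns ``(rd, var, corrected)`` arrays; the continuity correction is
    applied only in centers with a zero or full cell in either arm.
    """
    n_s = np.asarray(n_s, dtype=float)
    y_s = np.asarray(y_s, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    if np.any(n_s < 1) or np.any(n_t < 1):
        raise ValueError("every center needs at least one patient per arm")

    corrected = (y_s == 0) | (y_s == n_s) | (y_t == 0) | (y_t == n_t)
    ys = np.where(corrected, y_s + 0.5, y_s)
    ns = np.where(corrected, n_s + 1.0, n_s)
    yt = np.where(corrected, y_t + 0.5, y_t)
    nt = np.where(corrected, n_t + 1.0, n_t)

    p_s = ys / ns
    p_t = yt / nt
    rd = p_t - p_s
    var = p_t * (1.0 - p_t) / nt + p_s * (1.0 - p_s) / ns
    return rd, var, corrected


def center_effect(n_s: int, y_s: int, n_t: int, y_t: int) -> CenterEffect:
    """Risk difference and variance for a single center's 2x2 counts."""
    rd, var, corr = _center_effects(
        np.array([n_s]), np.array([y_s]), np.array([n_t]), np.array([y_t])
    )
    return CenterEffect(rd=float(rd[0]), var=float(var[0]), corrected=bool(corr[0]))


def _pool(rd: np.ndarray, var: np.ndarray) -> tuple[float, float, float]:
    """DerSimonian-Laird pooling: returns ``(mu, nu, tau2)``."""
    k = rd.size
    w = 1.0 / var
    sw = w.sum()
    rd_fe = (w * rd).sum() / sw
    if k == 1:
        tau2 = 0.0
    else:
        q = (w * (rd - rd_fe) ** 2).sum()
        denom = sw - (w * w).sum() / sw
        tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (var + tau2)
    sws = w_star.sum()
    mu = (w_star * rd).sum() / sws
    nu = 1.0 / sws
    return float(mu), float(nu), float(tau2)


def pool_random_effects(
    effects: Sequence[CenterEffect], alpha: float = 0.05
) -> REAnalysisResult:
    """Pool per-center risk differences with the DerSimonian-Laird estimator.

    With a single center the between-center variance is fixed at zero and the
    pooled estimate is that center's own.
    """
    if len(effects) < 1:
        raise ValueError("need at least one center")
    rd = np.array([e.rd for e in effects])
    var = np.array([e.var for e in effects])
    return _result_from_pool(*_pool(rd, var), alpha=alpha)


def _result_from_pool(mu: float, nu: float, tau2: float,
                      alpha: float = 0.05) -> REAnalysisResult:
    z = mu / math.sqrt(nu)
    # two-sided normal p-value via erfc, cheap enough for 1e5 replicate fits
    p = math.erfc(abs(z) / _SQRT2)
    return REAnalysisResult(mu=mu, nu=nu, tau2=tau2, z=z, p_value=p,
                            significant=p < alpha)


def significance_test(result: REAnalysisResult, alpha: float) -> bool:
    """Two-sided Wald test at level `alpha` (strict inequality)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return result.p_value < alpha


def analyze_trial(trial: SimulatedTrial, alpha: float = 0.05) -> REAnalysisResult:
    """Per-center effects plus DL pooling for a simulated or loaded trial."""
    rd, var, _ = _center_effects(trial.n_s, trial.y_s, trial.n_t, trial.y_t)
    return _result_from_pool(*_pool(rd, var), alpha=alpha)
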