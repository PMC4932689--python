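"""Empirical power, required-sample-size search, and the closed-form variance
of the pooled treatment effect under between-center variation.

Power is the fraction of simulated trials whose random-effects analysis is
significant. The required per-arm sample size is found by a monotone grid
search (default step 10 per arm) started at the classical two-proportion
approximation, which ignores the interaction and therefore underestimates n —
so the search typically brackets upward.

The closed-form variance of the estimated risk difference when each of K
centers randomizes n subjects (N = nK in total, both arms) is

    V = 2 (sigma_S^2 + sigma_T^2) / N + (v_S + v_T) / K,

with sigma_i^2 = pi_i (1 - pi_i) the within-arm binomial variance and
v_i = (pi_i CV_i)^2 the between-center variance of arm i's probability. The
first term shrinks with patients, the second only with centers — which is why
interaction inflates sample sizes most when centers are few.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import analyze_trial
from .trial import TrialDesign, simulate_trial

__all__ = [
    "PowerEstimate",
    "VarianceInputs",
    "SampleSizeResult",
    "SampleSizeSearchError",
    "estimate_power",
    "find_sample_size",
    "analytic_variance",
    "variance_sensitivity",
    "closed_form_n_no_interaction",
]


@dataclass(frozen=True)
class PowerEstimate:
    """Empirical power with its Monte Carlo standard error."""

    design: TrialDesign
    n_reps: int
    power: float
    seed: int

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.power * (1.0 - self.power) / self.n_reps)


@dataclass(frozen=True)
class VarianceInputs:
    """Inputs to the closed-form variance of the pooled risk difference."""

    pi_s: float
    pi_t: float
    cv_s: float
    cv_t: float
    k: int
    n_total: int

    @property
    def sigma2_s(self) -> float:
        return self.pi_s * (1.0 - self.pi_s)

    @property
    def sigma2_t(self) -> float:
        return self.pi_t * (1.0 - self.pi_t)

    @property
    def v_s(self) -> float:
        return (self.pi_s * self.cv_s) ** 2

    @property
    def v_t(self) -> float:
        return (self.pi_t * self.cv_t) ** 2


class SampleSizeSearchError(RuntimeError):
    """Raised when the grid search exhausts its bounds; carries the trace."""

    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


@dataclass
class SampleSizeResult:
    """Outcome of the required-sample-size grid search."""

    n_per_arm: int
    target_power: float
    step: int
    n_reps: int
    seed: int
    trace: pd.DataFrame = field(repr=False)


def _replicate_seed(seed: int, rep: int, stream: int = 0) -> np.random.SeedSequence:
    """Counter-based child seed: replicate `rep` of stream `stream`.

    Any replicate of any power estimate is reproducible in isolation, and
    distinct candidate sample sizes share no random streams.
    """
    return np.random.SeedSequence(entropy=seed, spawn_key=(stream, rep))


def estimate_power(
    design: TrialDesign,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
    _stream: int = 0,
) -> PowerEstimate:
    """Fraction of `n_reps` simulated trials that reach two-sided significance.

    Replicate ``r`` uses an independent child seed derived from ``seed`` and
    ``r``, so the estimate is reproducible and replicates are independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_replicate_seed(seed, rep, _stream))
        result = analyze_trial(simulate_trial(design, rng), alpha=alpha)
        hits += result.p_value < alpha
    return PowerEstimate(design=design, n_reps=n_reps,
                         power=hits / n_reps, seed=seed)


def closed_form_n_no_interaction(
    pi_s: float, pi_t: float, alpha: float = 0.05, power: float = 0.8
) -> float:
    """Classical two-proportion per-arm sample size (no interaction).

    ``(z_{1-alpha/2} + z_{power})^2 (pi_S(1-pi_S) + pi_T(1-pi_T)) / (pi_S - pi_T)^2``
    """
    if pi_s == pi_t:
        raise ValueError("pi_s and pi_t must differ")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    num = (z_a + z_b) ** 2 * (pi_s * (1.0 - pi_s) + pi_t * (1.0 - pi_t))
    return float(num / (pi_s - pi_t) ** 2)


def find_sample_size(
    design: TrialDesign,
    alpha: float = 0.05,
    target_power: float = 0.8,
    step: int = 10,
    n_reps: int = 10_000,
    seed: int = 0,
    max_n_per_arm: int = 100_000,
) -> SampleSizeResult:
    """Smallest per-arm sample size on the grid whose estimated power reaches
    `target_power`.

    The grid consists of multiples of `step`; the search starts at the
    closed-form no-interaction approximation (rounded up to the grid, floored
    at the smallest feasible size) and walks monotonically: up while power is
    short of target, or down while it still exceeds it. Each candidate size
    uses its own independent seed stream, so power estimates at different
    candidates share no random numbers. `design.n_total` is ignored; all other
    design fields are kept.

    Returns a :class:`SampleSizeResult` whose ``trace`` records every
    candidate evaluated.
    """
    if step < 1:
        raise ValueError("step must be >= 1")

    n_min = math.ceil(design.k_centers * design.min_per_center / 2 / step) * step
    try:
        n0 = closed_form_n_no_interaction(design.standard_arm.mean, design.pi_t,
                                          alpha, target_power)
    except ValueError:  # null design: no finite closed-form start
        n0 = 0.0
    n = max(n_min, math.ceil(n0 / step) * step)

    rows: list[dict] = []

    def power_at(n_per_arm: int) -> float:
        est = estimate_power(design.with_n_per_arm(n_per_arm), alpha=alpha,
                             n_reps=n_reps, seed=seed, _stream=n_per_arm)
        rows.append({"n_per_arm": n_per_arm, "reps": n_reps,
                     "power": est.power, "mc_se": est.mc_se})
        return est.power

    def trace() -> pd.DataFrame:
        return pd.DataFrame(rows, columns=["n_per_arm", "reps", "power", "mc_se"])

    p = power_at(n)
    if p >= target_power:
        # walk down until power drops below target; answer is the last n above
        while n - step >= n_min and power_at(n - step) >= target_power:
            n -= step
    else:
        while p < target_power:
            n += step
            if n > max_n_per_arm:
                raise SampleSizeSearchError(
                    f"no per-arm size <= {max_n_per_arm} reached power "
                    f"{target_power}", trace())
            p = power_at(n)

    return SampleSizeResult(n_per_arm=n, target_power=target_power, step=step,
                            n_reps=n_reps, seed=seed, trace=trace())


def analytic_variance(inputs: VarianceInputs) -> float:
    """Closed-form variance V of the estimated risk difference."""
    within = 2.0 * (inputs.sigma2_s + inputs.sigma2_t) / inputs.n_total
    between = (inputs.v_s + inputs.v_t) / inputs.k
    return within + between


def variance_sensitivity(
    base: VarianceInputs, cv_t_values: list[float]
) -> pd.DataFrame:
    """V and its percent increase over the ``cv_t = 0`` reference, per CV_T.

    The reference keeps every other input (including ``cv_s``) fixed.
    """
    import dataclasses

    v0 = analytic_variance(dataclasses.replace(base, cv_t=0.0))
    rows = []
    for cv_t in cv_t_values:
        v = analytic_variance(dataclasses.replace(base, cv_t=cv_t))
        rows.append({"cv_t": cv_t, "variance": v,
                     "pct_increase": 100.0 * (v / v0 - 1.0)})
    return pd.DataFrame(rows)
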