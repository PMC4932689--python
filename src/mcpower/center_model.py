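"""Between-center variation of an event probability as a moment-matched Beta law.

In a multicenter trial with a binary outcome, the control-arm event probability
is rarely identical across centers: referral patterns, co-interventions and
local practice all move it around. This module models that spread as a Beta
distribution on the per-center probability ``pi_i``, parameterized not by the
shape pair ``(a, b)`` directly but by the two quantities a trialist actually
elicits — the mean event probability ``E(pi_i)`` and its between-center
coefficient of variation ``CV(pi_i) = SD(pi_i) / E(pi_i)``.

Writing ``c = CV(pi_i)`` and ``d = E / (1 - E)`` (the odds of the mean), the
moment equations

    E(pi_i)  = a / (a + b)
    V(pi_i)  = a b / ((a + b)^2 (a + b + 1))

invert in closed form to

    a = (1 - c^2 d) / (c^2 (1 + d)),    b = (1 - c^2 d) / (c^2 d (1 + d)),

which is feasible exactly when ``c^2 < (1 - E) / E`` (a Beta variable on (0,1)
cannot have more relative spread than that). The degenerate case ``c = 0`` is
represented explicitly as a point mass at the mean rather than as a limiting
Beta, so that no-interaction designs are exact and numerically clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BetaSpec",
    "solve_beta_parameters",
    "beta_moments",
    "tail_probability",
    "quantiles",
    "sample_center_probabilities",
]

#: Tolerance used by the BetaSpec invariant checks.
_MOMENT_TOL = 1e-10


@dataclass(frozen=True)
class BetaSpec:
    """A Beta distribution for a per-center probability, carrying both
    parameterizations.

    Attributes
    ----------
    mean : float
        Mean event probability across centers, ``E(pi_i)``, in (0, 1).
    cv : float
        Between-center coefficient of variation of the probability,
        ``SD(pi_i) / E(pi_i)``. ``cv == 0`` marks a point mass at `mean`.
    a, b : float or None
        Beta shape parameters. ``None`` for the point-mass (``cv == 0``) case.
    """

    mean: float
    cv: float
    a: float | None
    b: float | None

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError(f"mean must lie in (0, 1), got {self.mean}")
        if self.cv < 0.0:
            raise ValueError(f"cv must be nonnegative, got {self.cv}")
        if self.is_point_mass:
            if self.a is not None or self.b is not None:
                raise ValueError("point-mass spec (cv == 0) must have a = b = None")
            return
        if self.a is None or self.b is None or self.a <= 0.0 or self.b <= 0.0:
            raise ValueError("Beta shape parameters must be positive")
        m, c = beta_moments(self)
        if abs(m - self.mean) > _MOMENT_TOL or abs(c - self.cv) > _MOMENT_TOL:
            raise ValueError(
                f"(a, b) = ({self.a}, {self.b}) are inconsistent with "
                f"(mean, cv) = ({self.mean}, {self.cv})"
            )

    @property
    def is_point_mass(self) -> bool:
        """True when the spec is degenerate (no between-center variation)."""
        return self.cv == 0.0

    @property
    def d(self) -> float:
        """Odds of the mean, ``d = E / (1 - E)``."""
        return self.mean / (1.0 - self.mean)

    @classmethod
    def from_shape(cls, a: float, b: float) -> "BetaSpec":
        """Build a spec from the Beta shape pair ``(a, b)`` directly."""
        if a <= 0.0 or b <= 0.0:
            raise ValueError("Beta shape parameters must be positive")
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return cls(mean=mean, cv=math.sqrt(var) / mean, a=a, b=b)

    # -- plain-JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {"mean": self.mean, "cv": self.cv, "a": self.a, "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "BetaSpec":
        return cls(mean=d["mean"], cv=d["cv"], a=d.get("a"), b=d.get("b"))


def solve_beta_parameters(mean: float, cv: float) -> BetaSpec:
    """Moment-match a Beta distribution to a (mean, CV) pair.

    Parameters
    ----------
    mean : float
        Target mean event probability, in (0, 1).
    cv : float
        Target coefficient of variation. ``cv = 0`` yields a point mass.

    Returns
    -------
    BetaSpec
        Spec whose Beta moments reproduce ``(mean, cv)`` to within 1e-10.

    Raises
    ------
    ValueError
        If ``cv**2 >= (1 - mean) / mean`` — no Beta distribution on (0, 1)
        attains that much relative spread at that mean.

    Examples
    --------
    >>> spec = solve_beta_parameters(0.3, 0.3)
    >>> round(spec.a, 3), round(spec.b, 2)
    (7.478, 17.45)
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if cv < 0.0:
        raise ValueError(f"cv must be nonnegative, got {cv}")
    if cv == 0.0:
        return BetaSpec(mean=mean, cv=0.0, a=None, b=None)
    bound = (1.0 - mean) / mean
    if cv * cv >= bound:
        raise ValueError(
            f"infeasible (mean, cv) = ({mean}, {cv}): a Beta distribution "
            f"requires cv**2 < (1 - mean)/mean = {bound:.6g}"
        )
    c2 = cv * cv
    d = mean / (1.0 - mean)
    a = (1.0 - c2 * d) / (c2 * (1.0 + d))
    b = (1.0 - c2 * d) / (c2 * d * (1.0 + d))
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError(
            f"cv = {cv} is too small to represent as a Beta shape pair in "
            "double precision; use cv = 0 for a point mass"
        )
    return BetaSpec(mean=mean, cv=cv, a=a, b=b)


def beta_moments(spec: BetaSpec) -> tuple[float, float]:
    """Return ``(mean, cv)`` implied by the spec's shape parameters.

    Round-trips :func:`solve_beta_parameters` to within 1e-10. A point-mass
    spec returns ``(mean, 0.0)``.
    """
    if spec.is_point_mass:
        return spec.mean, 0.0
    a, b = spec.a, spec.b
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1.0))
    return mean, math.sqrt(var) / mean


def tail_probability(spec: BetaSpec, threshold: float) -> float:
    """Probability that a center's event probability exceeds `threshold`.

    Computed as the upper tail of the regularized incomplete beta function,
    ``P(X > t) = 1 - I_t(a, b)``. For a point-mass spec the answer is the
    indicator ``mean > threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if spec.is_point_mass:
        return 1.0 if spec.mean > threshold else 0.0
    return float(stats.beta.sf(threshold, spec.a, spec.b))


def quantiles(spec: BetaSpec, probs: Sequence[float]) -> np.ndarray:
    """Quantiles of the between-center distribution.

    Inverts the regularized incomplete beta function at each probability in
    `probs`. A point-mass spec returns the mean at every probability.
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("quantile probabilities must lie strictly in (0, 1)")
    if spec.is_point_mass:
        return np.full(p.shape, spec.mean)
    return stats.beta.ppf(p, spec.a, spec.b)


def sample_center_probabilities(
    spec: BetaSpec, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw `k` per-center probabilities from the spec.

    Reproducible under identical generator state; a point-mass spec returns
    `k` copies of the mean without consuming random numbers.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if spec.is_point_mass:
        return np.full(k, spec.mean)
    return rng.beta(spec.a, spec.b, size=k)
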