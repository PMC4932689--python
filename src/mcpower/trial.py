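"""Simulation of one multicenter two-arm trial with a binary outcome.

One simulated trial proceeds in four steps, mirroring how the planned trial
would actually run:

1. the total sample is allocated at random among the ``K`` centers with equal
   probability per center, subject to a minimum number of patients per center
   (the minimum is assigned deterministically and only the surplus is
   multinomial, which honors the constraint without rejection sampling);
2. within each center patients are randomized 1:1 (stratified-blocked
   randomization collapses to an exact half/half split; an odd patient goes to
   either arm on a fair coin flip);
3. each center's control-arm ("standard") event probability is drawn from the
   between-center Beta law, or fixed at its mean when the CV is zero;
4. outcomes are Bernoulli — control patients at their center's drawn
   probability, treatment patients at a probability fixed across centers
   (optionally itself Beta-distributed, for robustness analyses).

Everything is reproducible from a single `numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .center_model import BetaSpec, sample_center_probabilities, solve_beta_parameters

__all__ = ["TrialDesign", "SimulatedTrial", "allocate_centers",
           "randomize_within_center", "simulate_trial"]


@dataclass(frozen=True)
class TrialDesign:
    """All parameters needed to simulate one multicenter two-arm trial.

    Attributes
    ----------
    k_centers : int
        Number of clinical centers, ``K`` (at least 2).
    n_total : int
        Total number of patients across both arms, ``N``.
    standard_arm : BetaSpec
        Between-center distribution of the control-arm event probability.
    pi_t : float
        Treatment-arm event probability, fixed across centers.
    min_per_center : int
        Minimum patients allocated to every center (default 6).
    treatment_arm_cv : float
        Optional between-center CV of the treatment-arm probability
        (default 0: no variation, the base modeling assumption).
    """

    k_centers: int
    n_total: int
    standard_arm: BetaSpec
    pi_t: float
    min_per_center: int = 6
    treatment_arm_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.k_centers < 2:
            raise ValueError("k_centers must be >= 2")
        if not 0.0 < self.pi_t < 1.0:
            raise ValueError(f"pi_t must lie in (0, 1), got {self.pi_t}")
        if self.n_total < self.k_centers * self.min_per_center:
            raise ValueError(
                f"n_total = {self.n_total} cannot place at least "
                f"{self.min_per_center} patients in each of {self.k_centers} centers"
            )
        if self.treatment_arm_cv < 0.0:
            raise ValueError("treatment_arm_cv must be nonnegative")

    @property
    def n_per_arm(self) -> float:
        return self.n_total / 2.0

    def treatment_spec(self) -> BetaSpec:
        """Between-center law of the treatment-arm probability."""
        return solve_beta_parameters(self.pi_t, self.treatment_arm_cv)

    def with_n_per_arm(self, n_per_arm: int) -> "TrialDesign":
        """Copy of the design with ``n_total = 2 * n_per_arm``."""
        return dataclasses.replace(self, n_total=2 * int(n_per_arm))


@dataclass
class SimulatedTrial:
    """Per-center counts of one simulated trial plus the latent probabilities.

    Arrays are aligned by center: ``n_s[i]`` patients and ``y_s[i]`` events in
    the control arm of center ``i``, ``n_t``/``y_t`` likewise for treatment,
    and ``pi_s[i]`` the latent control-arm probability the outcomes were drawn
    from.
    """

    n_s: np.ndarray
    y_s: np.ndarray
    n_t: np.ndarray
    y_t: np.ndarray
    pi_s: np.ndarray
    design: TrialDesign | None = None
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center": np.arange(1, len(self.n_s) + 1),
                "n_S": self.n_s,
                "y_S": self.y_s,
                "n_T": self.n_t,
                "y_T": self.y_t,
                "pi_S_latent": self.pi_s,
            }
        )

    def to_csv(self, path: str | Path | StringIO) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | StringIO) -> "SimulatedTrial":
        df = pd.read_csv(path, comment="#")
        return cls(
            n_s=df["n_S"].to_numpy(),
            y_s=df["y_S"].to_numpy(),
            n_t=df["n_T"].to_numpy(),
            y_t=df["y_T"].to_numpy(),
            pi_s=df.get("pi_S_latent", pd.Series(np.full(len(df), np.nan))).to_numpy(),
        )


def allocate_centers(
    n_total: int, k: int, min_per_center: int, rng: np.random.Generator
) -> np.ndarray:
    """Allocate `n_total` patients among `k` centers, each getting at least
    `min_per_center`.

    The minimum is placed in every center deterministically; the surplus
    ``n_total - k * min_per_center`` is distributed as an equal-probability
    multinomial.
    """
    if n_total < k * min_per_center:
        raise ValueError(
            f"cannot place {min_per_center} patients in each of {k} centers "
            f"with n_total = {n_total}"
        )
    surplus = n_total - k * min_per_center
    sizes = np.full(k, min_per_center, dtype=np.int64)
    if surplus > 0:
        sizes += rng.multinomial(surplus, np.full(k, 1.0 / k))
    return sizes


def randomize_within_center(
    center_size: int, rng: np.random.Generator
) -> tuple[int, int]:
    """1:1 randomization within a center: ``(n_standard, n_treatment)``.

    Even sizes split exactly in half; for odd sizes the extra patient's arm is
    a fair coin flip, keeping the arms exchangeable.
    """
    if center_size < 1:
        raise ValueError("center_size must be >= 1")
    n_s = center_size // 2
    if center_size % 2:
        n_s += int(rng.integers(0, 2))
    return n_s, center_size - n_s


def _split_arms(sizes: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1:1 split of every center; odd remainders by fair coin."""
    odd = sizes % 2
    coins = rng.integers(0, 2, size=sizes.shape)
    n_s = sizes // 2 + odd * coins
    return n_s, sizes - n_s


def simulate_trial(
    design: TrialDesign,
    rng: np.random.Generator | int | np.random.SeedSequence,
) -> SimulatedTrial:
    """Simulate one trial under `design`.

    Accepts a Generator, a seed, or a SeedSequence; with a fixed seed the
    result is bit-reproducible. Draw order: allocation, odd-size coin flips,
    latent control probabilities, latent treatment probabilities (only when
    ``treatment_arm_cv > 0``), control outcomes, treatment outcomes.
    """
    seed = rng if isinstance(rng, int) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    sizes = allocate_centers(design.n_total, design.k_centers,
                             design.min_per_center, rng)
    n_s, n_t = _split_arms(sizes, rng)
    pi_s = sample_center_probabilities(design.standard_arm, design.k_centers, rng)
    if design.treatment_arm_cv > 0.0:
        pi_t = sample_center_probabilities(design.treatment_spec(),
                                           design.k_centers, rng)
    else:
        pi_t = np.full(design.k_centers, design.pi_t)
    y_s = rng.binomial(n_s, pi_s)
    y_t = rng.binomial(n_t, pi_t)
    return SimulatedTrial(n_s=n_s, y_s=y_s, n_t=n_t, y_t=y_t, pi_s=pi_s,
                          design=design, seed=seed)
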