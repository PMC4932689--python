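"""Bayesian decision model linking a surrogate endpoint to a rare clinical one.

A trial powered for a surrogate outcome (preterm birth, at or before 33+6
weeks) cannot directly compare arms on a rare clinical outcome (perinatal
mortality / serious neonatal morbidity). Writing pi_ptb|T and pi_ptb|S for the
arm-specific preterm probabilities and tau_pmm|ptb, tau_pmm|tb for the
probability of the clinical outcome in preterm and term babies, the
between-arm difference in the clinical outcome's probability factorizes as

    Delta = (pi_ptb|T - pi_ptb|S) * (tau_pmm|ptb - tau_pmm|tb),

because the term-birth probabilities enter only as 1 - pi_ptb|arm. The two
link probabilities get conjugate Beta posteriors from external cohort counts
(a Beta(1, 1) prior plus binomial data), the surrogate effect gets a
Normal(mu, nu) posterior from the trial's random-effects analysis, and Delta's
posterior is sampled by Monte Carlo. The decision quantity is P(Delta < 0) —
the posterior probability that treatment reduces the clinical outcome.

`MACS_COUNTS` bundles the external cohort used throughout: among 1463
singleton pregnancies, 530 preterm births with 166 clinical events, and 933
term births with 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import analyze_trial
from .trial import TrialDesign, simulate_trial

__all__ = [
    "SurrogateLinkData",
    "DeltaModel",
    "DecisionResult",
    "DecisionPerformance",
    "MACS_COUNTS",
    "beta_posterior",
    "point_estimates",
    "sample_delta",
    "decision_summary",
    "evaluate_decision_performance",
]


@dataclass(frozen=True)
class SurrogateLinkData:
    """Counts relating surrogate status to the clinical outcome.

    ``n_ptb`` preterm births with ``y_ptb`` clinical events; ``n_tb`` term
    births with ``y_tb`` events.
    """

    n_ptb: int
    y_ptb: int
    n_tb: int
    y_tb: int

    def __post_init__(self) -> None:
        if not (0 <= self.y_ptb <= self.n_ptb and 0 <= self.y_tb <= self.n_tb):
            raise ValueError("event counts must satisfy 0 <= y <= n in each stratum")

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateLinkData":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return {"n_ptb": self.n_ptb, "y_ptb": self.y_ptb,
                "n_tb": self.n_tb, "y_tb": self.y_tb}


#: Singleton-pregnancy counts from the MACS antenatal-corticosteroids cohort.
MACS_COUNTS = SurrogateLinkData(n_ptb=530, y_ptb=166, n_tb=933, y_tb=5)


def beta_posterior(
    y: int, n: int, prior_a: float = 1.0, prior_b: float = 1.0
) -> tuple[float, float]:
    """Conjugate Beta posterior ``(prior_a + y, prior_b + n - y)``."""
    if not 0 <= y <= n:
        raise ValueError("need 0 <= y <= n")
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError("prior parameters must be positive")
    return prior_a + y, prior_b + n - y


def point_estimates(data: SurrogateLinkData) -> tuple[float, float]:
    """(P(event | preterm), P(no event | term)) as simple ratios."""
    if data.n_ptb == 0 or data.n_tb == 0:
        raise ValueError("both strata need at least one observation")
    return data.y_ptb / data.n_ptb, (data.n_tb - data.y_tb) / data.n_tb


@dataclass(frozen=True)
class DeltaModel:
    """Posterior ingredients of the Delta decomposition.

    ``tau_ptb_posterior`` / ``tau_tb_posterior`` are Beta shape pairs for the
    clinical-outcome probability given preterm / term birth; ``mu``/``nu`` are
    the Normal posterior mean and variance of the surrogate risk difference.
    """

    tau_ptb_posterior: tuple[float, float]
    tau_tb_posterior: tuple[float, float]
    mu: float
    nu: float

    def __post_init__(self) -> None:
        if self.nu <= 0.0:
            raise ValueError("nu must be positive")
        for a, b in (self.tau_ptb_posterior, self.tau_tb_posterior):
            if a <= 0 or b <= 0:
                raise ValueError("Beta posterior parameters must be positive")

    @classmethod
    def from_link(
        cls,
        link: SurrogateLinkData,
        mu: float,
        nu: float,
        prior: tuple[float, float] = (1.0, 1.0),
    ) -> "DeltaModel":
        """Build the model from link counts and a surrogate-effect posterior."""
        return cls(
            tau_ptb_posterior=beta_posterior(link.y_ptb, link.n_ptb, *prior),
            tau_tb_posterior=beta_posterior(link.y_tb, link.n_tb, *prior),
            mu=mu,
            nu=nu,
        )


@dataclass(frozen=True)
class DecisionResult:
    """Posterior summary of Delta from Monte Carlo samples."""

    prob_delta_negative: float
    credible_interval: tuple[float, float]
    n_samples: int
    seed: int | None = None


def sample_delta(
    model: DeltaModel, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte Carlo draws of Delta.

    Each draw multiplies one Normal(mu, nu) surrogate-effect draw by the
    difference of independent draws from the two Beta link posteriors. Draw
    order: normal effect, tau(preterm), tau(term).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    effect = rng.normal(model.mu, np.sqrt(model.nu), size=n_samples)
    tau_ptb = rng.beta(*model.tau_ptb_posterior, size=n_samples)
    tau_tb = rng.beta(*model.tau_tb_posterior, size=n_samples)
    return effect * (tau_ptb - tau_tb)


def decision_summary(
    samples: np.ndarray, interval_mass: float = 0.95, seed: int | None = None
) -> DecisionResult:
    """P(Delta < 0) and an equal-tailed credible interval from samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be nonempty")
    if not 0.0 < interval_mass < 1.0:
        raise ValueError("interval_mass must lie in (0, 1)")
    lo = 100.0 * (1.0 - interval_mass) / 2.0
    low, high = np.percentile(samples, [lo, 100.0 - lo])
    return DecisionResult(
        prob_delta_negative=float(np.mean(samples < 0.0)),
        credible_interval=(float(low), float(high)),
        n_samples=int(samples.size),
        seed=seed,
    )


@dataclass
class DecisionPerformance:
    """Operating characteristics of the decision analysis over many trials."""

    mean_prob_negative: float
    pct5_prob_negative: float
    n_trials: int
    n_samples: int
    seed: int
    records: pd.DataFrame = field(repr=False)


def evaluate_decision_performance(
    design: TrialDesign,
    link: SurrogateLinkData,
    n_trials: int = 1000,
    n_samples: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> DecisionPerformance:
    """Nested simulation of the decision analysis' operating characteristics.

    Each replicate simulates a full trial under `design`, fits the
    random-effects risk-difference model to get the surrogate posterior
    Normal(mu, nu), samples Delta `n_samples` times against the link
    posteriors, and records the fraction of negative draws. Summaries are the
    mean and empirical 5th percentile of that fraction across trials.
    """
    if n_trials < 1 or n_samples < 1:
        raise ValueError("n_trials and n_samples must be >= 1")
    rows = []
    for t in range(n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(t,))
        )
        trial = simulate_trial(design, rng)
        fit = analyze_trial(trial, alpha=alpha)
        model = DeltaModel.from_link(link, mu=fit.mu, nu=fit.nu)
        frac_neg = float(np.mean(sample_delta(model, n_samples, rng) < 0.0))
        rows.append({"trial": t, "mu": fit.mu, "nu": fit.nu,
                     "tau2": fit.tau2, "prob_delta_negative": frac_neg})
    records = pd.DataFrame(rows)
    probs = records["prob_delta_negative"].to_numpy()
    return DecisionPerformance(
        mean_prob_negative=float(probs.mean()),
        pct5_prob_negative=float(np.percentile(probs, 5.0)),
        n_trials=n_trials,
        n_samples=n_samples,
        seed=seed,
        records=records,
    )
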