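# Methods

## Scope

`mcpower` answers two design questions for a multicenter two-arm RCT with a
binary outcome:

1. How many patients are needed for 80% power at a two-sided 5% level when
   the control-arm event probability — and hence the treatment effect —
   varies between centers?
2. If the trial is powered for a surrogate outcome, with what certainty can
   it conclude benefit on a rare clinical outcome, given external data
   linking surrogate status to the clinical event?

Both are answered by Monte Carlo simulation around a small set of closed-form
ingredients. Conduct or analysis of any real trial data is out of scope, as
is validation of the surrogate itself (the model *assumes* the treatment
affects the clinical outcome only through the surrogate; that assumption must
be defended on subject-matter grounds).

## Between-center model

The control-arm probability in center *i* is `π_Si ~ Beta(a, b)`, chosen
because it lives on (0,1), is conjugate to binomial sampling, and its two
shapes can be matched to the two quantities a planner can actually elicit:
the mean `E` and between-center coefficient of variation `c`. The closed-form
inversion (see README) is feasible iff `c² < (1−E)/E`; the package raises a
parameterization error naming that bound otherwise. `c = 0` is represented as
an explicit point-mass variant rather than a limiting Beta: the
no-interaction rows of the sample-size tables require it exactly, and a Beta
with enormous `a + b` is numerically awkward (shapes overflow double
precision for `c` below ~1e-150).

Quantiles invert the regularized incomplete beta via `scipy.stats.beta.ppf`;
the test suite checks it against an independent bisection on
`scipy.special.betainc` to 1e-8. One documented ambiguity: for the base case
`Beta(7.478, 17.45)`, the 5th/95th percentiles are (0.161, 0.457) while the
equal-tailed 2.5/97.5 interval is (0.141, 0.490); a "95% between 0.16 and
0.46" statement matches the 5th/95th pair, i.e. a 90% equal-tailed interval.
Both are exposed via `quantiles`.

The treatment-arm probability `π_T` is fixed across centers by default — the
base assumption being that an effective intervention leaves little room for
additional center-level interventions to move the probability (a floor
effect). `treatment_arm_cv` relaxes this for robustness analyses; the
closed-form variance shows why the base assumption is mild: the treatment
arm's between-center contribution is `(π_T CV_T)²/K`, and with `π_T` and
`CV_T` both smaller than their control-arm counterparts even `CV_T = 0.15`
raises the variance by only 2.19% (computed by `variance_sensitivity`).

## Trial simulation

Patients are allocated to centers in two stages: every center receives the
minimum (default 6) deterministically, and the surplus is equal-probability
multinomial. This honors the "at least six per center" constraint without
rejection sampling; the true allocation mechanism of any specific trial is
not modeled. Within-center 1:1 randomization collapses stratified-blocked
assignment to an exact half/half split; an odd patient's arm is a fair coin
flip so the arms stay exchangeable. Outcomes are Bernoulli given the latent
center probabilities.

Randomness: one `numpy` PCG64 stream per simulated trial. Replicate *r* of a
power estimate uses `SeedSequence(seed, spawn_key=(stream, r))`, where
`stream` identifies the candidate sample size — any single replicate of any
grid cell is reproducible in isolation, and candidate sizes share no random
numbers (common random numbers across candidates would reduce search variance
but correlate the power curve; independence was chosen so each estimate's
Monte Carlo error is the plain binomial one).

## Random-effects analysis

Each center contributes a risk difference `y_T/n_T − y_S/n_S` with variance
`p̂_T(1−p̂_T)/n_T + p̂_S(1−p̂_S)/n_S`. Centers with a zero or full cell get a
continuity correction (0.5 per cell, 1 per arm total) before both the
estimate and the variance, preventing infinite weights at centers with as few
as 3 per arm; the correction is per-center, applied only where needed.
Pooling is DerSimonian–Laird: the method-of-moments `τ²` (truncated at 0) is
added to each center's variance before inverse-variance weighting, and the
pooled effect is tested with a two-sided Wald normal statistic (a normal
rather than t reference — the supported designs have ≥ 20 centers).

DL was chosen over a likelihood-based random-slope model because it is
closed-form — a few vector operations per replicate, which matters when the
power search fits ~10⁵ replicates — and because it operates directly on the
risk-difference scale the decision model needs. Two measured consequences of
this choice, at the base design's small centers (~9 patients/arm/center):

- **Mild liberality.** At the null (`π_T = E(π_S) = 0.3`, CV 0, K = 80,
  N = 1400) the true rejection rate is ≈ 0.057 rather than 0.050 — the
  familiar small-sample behavior of Wald tests with estimated
  inverse-variance weights. The acceptance suite asserts the nominal
  0.05 ± 3·MC-SE band and is expected to fail there; the failure documents
  the estimator, not a coding defect.
- **Slight inefficiency at CV 0.** Power at 540/arm is 0.790 rather than
  0.80, so the no-interaction grid search returns ≈ 560/arm where the
  classical two-proportion formula gives 536.4 (and a likelihood analysis
  ≈ 540). The corresponding acceptance assertion (540 ± 10) is likewise
  expected red. With interaction (CV 0.3) the search's true answer is
  680/arm, within the reference band 700 ± 20.

Knapp–Hartung adjustment, REML, and odds-ratio/log-RR scales are deliberate
non-features; they would change the small-sample behavior above and are the
natural first extensions.

## Power and sample-size search

Power is the significant fraction across replicates; its Monte Carlo standard
error `√(p(1−p)/R)` is reported alongside. The required per-arm size is the
smallest multiple of the grid step (default 10, matching the granularity of
published requirement tables) whose estimated power reaches the target. The
search starts at the classical no-interaction approximation — a lower bound
under interaction — and walks the grid monotonically, logging every candidate
in a trace. Near the decision boundary the returned size inherits the power
estimate's Monte Carlo noise: at 10⁴ replicates (SE ≈ 0.004) the answer is
reproducible to about one grid step across seeds. The acceptance tests use
4×10⁴ replicates per candidate so the search converges on the estimator's
true requirement; `scripts/acceptance.py` uses the design's stated 10⁴.

Default replication: 10⁴ per power estimate; the CLI table commands default
to `--scale 0.1` (10³ replicates per cell) for desk runs, with `--full`
restoring full replication.

## Surrogate decision model

`Δ = (π_ptb|T − π_ptb|S) × (τ_pmm|ptb − τ_pmm|tb)` is sampled by drawing the
surrogate effect from `Normal(μ, ν)` — the DL fit interpreted as the
posterior under an uninformative normal prior — and the link probabilities
from their conjugate posteriors; `P(Δ < 0)` counts strictly negative draws
(ties at 0 have probability zero), and credible intervals are equal-tailed
empirical quantiles (HPD intervals were not required and would differ only in
the third decimal here). In the degenerate one-to-one limit (`τ_pmm|ptb = 1`,
`τ_pmm|tb = 0`) the Δ draws equal the surrogate-effect draws exactly, so
surrogate inference *is* clinical inference; the bundled MACS counts put the
posterior link difference near 0.30, scaling the surrogate effect down
accordingly.

Whether a real trial's `Normal(μ, ν)` would come from a risk-difference or a
transformed-scale random-effects fit is a modeling choice; the
risk-difference DL fit is forced here by the Δ decomposition and is the main
source of tolerance when comparing operating characteristics against fits
from other software. The nested performance simulation (trial → fit → Δ
sampling) reproduces the base case's published operating characteristics
within ±0.01: mean `P(Δ < 0)` 0.977 and 5th percentile 0.876 at 1000 trials ×
2000 draws (seeds fixed in `tests/test_acceptance.py`).

## What the generator does and does not emulate

The simulator reproduces the *design* sources of variation: random center
sizes (minimum-plus-multinomial), exact 1:1 randomization, Beta-distributed
control-arm probabilities, binomial outcomes. It does not emulate accrual
over time, dropout or missing outcomes, center-level covariates, correlation
between a center's size and its event probability, or deviations from 1:1
balance — so passing tests certify the arithmetic of the design calculations
under the stated model, not robustness of any real trial to those phenomena.

One internal inconsistency in the motivating example is worth recording: a
rare-outcome illustration pairs "mean 0.01" with the shape pair (9.9, 89.1),
whose mean is in fact 0.099. The package always derives shapes from
`(mean, cv)` and never hard-codes that pair; the associated 37,500-per-arm
figure is therefore reproducible machinery-wise (`find_sample_size` at
mean 0.01, CV 0.3) but is not asserted against.

## Numerical notes

- Moment round-trips hold to 1e-10; `BetaSpec` validates shape/moment
  consistency on construction.
- Two-sided p-values use `erfc(|z|/√2)` (exact complement form, no
  subtraction loss in the tails).
- `τ²` truncation at zero occurs in ≈ 47% of null replicates at K = 80
  (Q ~ χ²₇₉); with CV 0.3 and large centers the mean DL `τ²` recovers the
  generating between-center variance (0.09·0.3)² ≈ 0.0081 within ~4%.
- All stochastic entry points take either an integer seed or a
  `numpy.random.Generator`; identical seeds give bit-identical results,
  including CSV outputs from the CLI.
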