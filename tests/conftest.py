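import numpy as np
import pytest

from mcpower import BetaSpec, TrialDesign, solve_beta_parameters


@pytest.fixture(scope="session")
def base_spec() -> BetaSpec:
    """Control-arm between-center law of the base design: mean 0.3, CV 0.3."""
    return solve_beta_parameters(0.3, 0.3)


@pytest.fixture(scope="session")
def point_spec() -> BetaSpec:
    """Degenerate (no-interaction) control-arm law at mean 0.3."""
    return solve_beta_parameters(0.3, 0.0)


@pytest.fixture(scope="session")
def base_design(base_spec) -> TrialDesign:
    """Base trial design: 80 centers, 700 per arm, treatment probability 0.225."""
    return TrialDesign(k_centers=80, n_total=1400, standard_arm=base_spec,
                       pi_t=0.225)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_160_705)
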