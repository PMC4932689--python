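"""Bayesian surrogate-to-clinical decision model."""

import numpy as np
import pytest
from scipy import stats

from mcpower import (
    MACS_COUNTS,
    DeltaModel,
    SurrogateLinkData,
    TrialDesign,
    beta_posterior,
    decision_summary,
    evaluate_decision_performance,
    point_estimates,
    sample_delta,
)


class TestBetaPosterior:
    def test_macs_preterm_stratum(self):
        assert beta_posterior(166, 530) == (167, 365)

    def test_macs_term_stratum(self):
        assert beta_posterior(5, 933) == (6, 929)

    def test_no_data_returns_prior(self):
        assert beta_posterior(0, 0) == (1, 1)

    def test_updating_is_additive(self):
        a1, b1 = beta_posterior(3, 10)
        once = beta_posterior(4, 12, prior_a=a1, prior_b=b1)
        assert once == beta_posterior(7, 22)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            beta_posterior(5, 3)


class TestPointEstimates:
    def test_macs_fixture(self):
        p_event, p_free = point_estimates(MACS_COUNTS)
        assert round(p_event, 2) == 0.31
        assert round(p_free, 2) == 0.99

    def test_degenerate_strata(self):
        assert point_estimates(SurrogateLinkData(10, 0, 10, 0)) == (0.0, 1.0)
        assert point_estimates(SurrogateLinkData(10, 10, 10, 10)) == (1.0, 0.0)


class TestSampleDelta:
    def test_null_surrogate_effect_splits_evenly(self, rng):
        # tau_ptb > tau_tb with overwhelming posterior probability under MACS,
        # so the sign of Delta is the sign of the (symmetric) normal draw
        model = DeltaModel.from_link(MACS_COUNTS, mu=0.0, nu=1e-4)
        draws = sample_delta(model, 40_000, rng)
        frac_neg = np.mean(draws < 0)
        assert abs(frac_neg - 0.5) < 3 * np.sqrt(0.25 / 40_000)

    def test_tau_difference_positive_by_numeric_integration(self):
        # P(tau_ptb > tau_tb) under the MACS posteriors, by quadrature
        grid = np.linspace(0, 1, 4001)
        f_ptb = stats.beta(167, 365).pdf(grid)
        cdf_tb = stats.beta(6, 929).cdf(grid)
        p = np.trapezoid(f_ptb * cdf_tb, grid)
        assert p > 1 - 1e-9

    def test_negative_mu_tiny_nu_gives_all_negative(self, rng):
        model = DeltaModel.from_link(MACS_COUNTS, mu=-0.075, nu=1e-18)
        assert np.all(sample_delta(model, 1000, rng) < 0)

    def test_negating_mu_mirrors_distribution(self):
        # mirroring holds in distribution (paired seeds share the same normal
        # deviates z, so draw-by-draw equality is not expected)
        m_pos = DeltaModel.from_link(MACS_COUNTS, mu=0.05, nu=2e-4)
        m_neg = DeltaModel.from_link(MACS_COUNTS, mu=-0.05, nu=2e-4)
        d_pos = sample_delta(m_pos, 5000, np.random.default_rng(4))
        d_neg = sample_delta(m_neg, 5000, np.random.default_rng(4))
        ks = stats.ks_2samp(d_pos, -d_neg)
        assert ks.pvalue > 0.01
        assert np.mean(d_pos < 0) + np.mean(d_neg < 0) == pytest.approx(1.0, abs=0.03)

    def test_monotone_in_mu(self):
        fracs = []
        for mu in np.linspace(0.05, -0.15, 20):
            model = DeltaModel.from_link(MACS_COUNTS, mu=float(mu), nu=4e-4)
            draws = sample_delta(model, 2000, np.random.default_rng(99))
            fracs.append(np.mean(draws < 0))
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestDecisionSummary:
    def test_half_negative(self):
        res = decision_summary(np.array([-1.0, -1.0, 1.0, 1.0]))
        assert res.prob_delta_negative == 0.5

    def test_all_negative_interval_below_zero(self):
        res = decision_summary(-np.abs(np.random.default_rng(0).normal(size=500)) - 0.1)
        assert res.prob_delta_negative == 1.0
        assert res.credible_interval[1] < 0

    def test_standard_normal_quantile_oracle(self, rng):
        res = decision_summary(rng.normal(size=100_000), interval_mass=0.95)
        assert res.credible_interval[0] == pytest.approx(-1.96, abs=0.02)
        assert res.credible_interval[1] == pytest.approx(1.96, abs=0.02)

    def test_interval_endpoints_are_order_statistics(self, rng):
        samples = rng.normal(size=999)
        res = decision_summary(samples, interval_mass=0.9)
        assert res.credible_interval[0] >= samples.min()
        assert res.credible_interval[1] <= samples.max()
        assert res.credible_interval[0] <= res.credible_interval[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            decision_summary(np.array([]))


class TestDegenerateLink:
    def test_one_to_one_correspondence_recovers_surrogate_effect(self, rng):
        """With P(event|preterm) = 1 and P(event|term) = 0 the clinical-effect
        draws equal the surrogate-effect draws exactly."""
        model = DeltaModel(
            tau_ptb_posterior=(1e9, 1e-9),  # point mass at 1 (up to fp)
            tau_tb_posterior=(1e-9, 1e9),  # point mass at 0
            mu=-0.075,
            nu=2e-4,
        )
        state = rng.bit_generator.state
        draws = sample_delta(model, 2000, rng)
        rng.bit_generator.state = state
        effect = rng.normal(-0.075, np.sqrt(2e-4), 2000)
        np.testing.assert_allclose(draws, effect, atol=1e-7)


class TestPerformanceEvaluation:
    def test_single_trial_summaries_equal_that_trial(self, base_design):
        perf = evaluate_decision_performance(base_design, MACS_COUNTS,
                                             n_trials=1, n_samples=500, seed=3)
        rec = perf.records["prob_delta_negative"].iloc[0]
        assert perf.mean_prob_negative == rec
        assert perf.pct5_prob_negative == rec

    def test_null_treatment_effect_centers_near_half(self, base_spec):
        design = TrialDesign(k_centers=80, n_total=1400,
                             standard_arm=base_spec, pi_t=0.3)
        perf = evaluate_decision_performance(design, MACS_COUNTS,
                                             n_trials=150, n_samples=500, seed=6)
        assert perf.mean_prob_negative == pytest.approx(0.5, abs=0.05)

    def test_records_carry_fit_and_fraction(self, base_design):
        perf = evaluate_decision_performance(base_design, MACS_COUNTS,
                                             n_trials=5, n_samples=200, seed=1)
        assert list(perf.records.columns) == [
            "trial", "mu", "nu", "tau2", "prob_delta_negative"
        ]
        assert len(perf.records) == 5
        assert perf.records["nu"].gt(0).all()
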