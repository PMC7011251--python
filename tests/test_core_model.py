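"""Closed-form and brute-force checks of the cure-rate Gompertz model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from emergebayes import (
    EmergenceDataset,
    ModelParams,
    PriorSpec,
    gompertz_cdf,
    gompertz_quantile,
    log_interval_prob,
    log_likelihood,
    log_posterior_unnorm,
    log_prior,
    median_emergence_time,
)


def _F(t, B, C):
    """Independent closed-form emergence CDF used as oracle throughout."""
    return math.exp(-math.exp(-B * (t - C)))


# ---------------------------------------------------------------------------
# Emergence function
# ---------------------------------------------------------------------------

class TestGompertzCdf:
    @pytest.mark.parametrize(
        "B, C, t, expected",
        [
            (2.0, 5.0, 5.0, math.exp(-1)),  # at the half-time the CDF is 1/e
            (2.0, 5.0, 6.0, math.exp(-math.exp(-2))),
            (2.0, 5.0, 1e6, 1.0),  # right limit
            (3.0, 8.0, 0.0, math.exp(-math.exp(24))),  # left tail ~ 0
        ],
    )
    def test_closed_form(self, B, C, t, expected):
        assert gompertz_cdf(ModelParams(1.0, B, C), t) == pytest.approx(
            expected, abs=1e-12
        )

    def test_negative_time_is_domain_error(self):
        with pytest.raises(ValueError):
            gompertz_cdf(ModelParams(1.0, 2.0, 5.0), -0.5)

    def test_monotone_in_t_and_antitone_in_C(self):
        t = np.linspace(0.0, 15.0, 100)
        p = ModelParams(1.0, 1.6, 4.3)
        F = gompertz_cdf(p, t)
        assert np.all(np.diff(F) >= 0)
        F_later = gompertz_cdf(ModelParams(1.0, 1.6, 6.0), t)
        assert np.all(F_later <= F)

    def test_quantile_inverts_cdf(self):
        p = ModelParams(1.0, 1.6, 4.3)
        for q in (0.01, 0.5, 0.99):
            assert gompertz_cdf(p, gompertz_quantile(p, q)) == pytest.approx(q)

    def test_median_exceeds_half_time(self):
        # F(C) = 1/e < 1/2, so the true median lies beyond C
        p = ModelParams(1.0, 1.6, 4.3)
        t50 = float(median_emergence_time(p.B, p.C))
        assert t50 > p.C
        assert gompertz_cdf(p, t50) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Interval probabilities
# ---------------------------------------------------------------------------

class TestLogIntervalProb:
    def test_total_mass_of_live_seed(self):
        p = ModelParams(1.0, 2.0, 5.0)
        assert log_interval_prob(p, 0.0, np.inf) == pytest.approx(0.0, abs=1e-10)

    def test_cure_fraction_never_emerges(self):
        p = ModelParams(0.0, 2.0, 5.0)
        assert log_interval_prob(p, 1.0, 2.0) == -np.inf

    def test_closed_form_difference(self):
        p = ModelParams(1.0, 2.0, 5.0)
        expected = math.log(_F(6, 2, 5) - _F(5, 2, 5))
        assert log_interval_prob(p, 5.0, 6.0) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_interval_is_domain_error(self):
        p = ModelParams(1.0, 2.0, 5.0)
        with pytest.raises(ValueError):
            log_interval_prob(p, 6.0, 6.0)
        with pytest.raises(ValueError):
            log_interval_prob(p, 6.0, 5.0)

    def test_right_tail_stays_finite_where_naive_subtraction_underflows(self):
        p = ModelParams(1.0, 2.0, 5.0)
        assert _F(51, 2, 5) - _F(50, 2, 5) == 0.0  # naive route underflows
        val = log_interval_prob(p, 50.0, 51.0)
        assert np.isfinite(val)
        # leading behaviour log(a_lo) = -B (t_lo - C)
        assert val == pytest.approx(-2.0 * 45.0, rel=1e-2)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class TestLogLikelihood:
    def test_empty_dataset_is_log_one(self):
        empty = EmergenceDataset(edges=[0.0], counts=[], n_censored=0)
        assert log_likelihood(ModelParams(0.5, 2.0, 5.0), empty) == 0.0

    def test_single_censored_seed(self):
        data = EmergenceDataset(edges=[0.0, 144.0], counts=[0], n_censored=1)
        got = log_likelihood(ModelParams(1.0, 2.0, 5.0), data)
        assert got == pytest.approx(math.log(1.0 - _F(6, 2, 5)), rel=1e-12)

    def test_emerged_seed_impossible_under_pure_cure(self, toy_tray):
        assert log_likelihood(ModelParams(0.0, 2.0, 5.0), toy_tray) == -np.inf

    def test_matches_per_seed_product(self, toy_tray):
        """Brute-force oracle: multiply the three per-seed factors directly."""
        alpha, B, C = 0.9, 1.0, 1.5
        factors = [
            alpha * (_F(1.0, B, C) - _F(0.0, B, C)),
            alpha * (_F(2.0, B, C) - _F(1.0, B, C)),
            (1 - alpha) + alpha * (1 - _F(2.0, B, C)),
        ]
        expected = sum(math.log(f) for f in factors)
        got = log_likelihood(ModelParams(alpha, B, C), toy_tray)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_full_yield_reduces_to_plain_interval_censored_likelihood(self):
        """With alpha = 1 and no censoring the cure factor disappears."""
        data = EmergenceDataset(edges=[0.0, 48.0, 96.0, 144.0],
                                counts=[3, 5, 2], n_censored=0)
        B, C = 1.2, 2.5
        edges_d = [0.0, 2.0, 4.0, 6.0]
        plain = sum(
            n * math.log(_F(hi, B, C) - _F(lo, B, C))
            for n, lo, hi in zip([3, 5, 2], edges_d[:-1], edges_d[1:])
        )
        assert log_likelihood(ModelParams(1.0, B, C), data) == pytest.approx(plain)

    def test_invariant_under_empty_intervals(self):
        """Prepending, appending (with M = 0) or splitting zero-count
        intervals leaves the likelihood unchanged."""
        p = ModelParams(0.9, 1.6, 4.3)
        base = EmergenceDataset(edges=[24.0, 48.0, 96.0], counts=[4, 6], n_censored=0)
        prepended = EmergenceDataset(edges=[0.0, 24.0, 48.0, 96.0],
                                     counts=[0, 4, 6], n_censored=0)
        appended = EmergenceDataset(edges=[24.0, 48.0, 96.0, 200.0],
                                    counts=[4, 6, 0], n_censored=0)
        assert log_likelihood(p, prepended) == pytest.approx(log_likelihood(p, base))
        assert log_likelihood(p, appended) == pytest.approx(log_likelihood(p, base))

    def test_sum_order_does_not_matter(self, sim_tray):
        """The log likelihood is the same sum of factors in any order."""
        p = ModelParams(0.9, 1.6, 4.3)
        edges_d = sim_tray.edges / 24.0
        rng = np.random.default_rng(0)
        order = rng.permutation(sim_tray.n_intervals)
        total = sum(
            sim_tray.counts[i] * math.log(
                p.alpha * (_F(edges_d[i + 1], p.B, p.C) - _F(edges_d[i], p.B, p.C))
            )
            for i in order if sim_tray.counts[i]
        )
        total += sim_tray.n_censored * math.log(
            1 - p.alpha * _F(edges_d[-1], p.B, p.C)
        )
        assert log_likelihood(p, sim_tray) == pytest.approx(total, rel=1e-12)

    def test_all_censored_tray_is_legal(self):
        data = EmergenceDataset(edges=[0.0, 288.0], counts=[0], n_censored=110)
        val = log_likelihood(ModelParams(0.5, 1.6, 4.3), data)
        assert np.isfinite(val)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    alpha=st.floats(0.0, 1.0),
    B=st.floats(0.1, 5.0),
    C=st.floats(0.5, 10.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_partition_of_seed_fate_normalizes(alpha, B, C, seed):
    """Emerging in some interval, emerging before the window, and not
    emerging at all are exhaustive and exclusive outcomes of one seed."""
    rng = np.random.default_rng(seed)
    edges_d = np.sort(rng.uniform(0.0, 20.0, size=rng.integers(2, 30)))
    edges_d = np.unique(edges_d)
    if edges_d.size < 2:
        edges_d = np.array([1.0, 2.0])
    p = ModelParams(alpha, B, C)
    with np.errstate(all="ignore"):
        interval_mass = sum(
            math.exp(log_interval_prob(p, lo, hi))
            for lo, hi in zip(edges_d[:-1], edges_d[1:])
        )
    censored_mass = 1.0 - alpha * gompertz_cdf(p, edges_d[-1])
    early_mass = alpha * gompertz_cdf(p, edges_d[0])
    assert interval_mass + censored_mass + early_mass == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# Priors and posterior density
# ---------------------------------------------------------------------------

class TestLogPrior:
    def test_outside_truncated_support(self, default_prior):
        bad_B = ModelParams(0.5, -1.0, 5.0, validate=False)
        bad_C = ModelParams(0.5, 2.0, -0.1, validate=False)
        assert log_prior(default_prior, bad_B) == -np.inf
        assert log_prior(default_prior, bad_C) == -np.inf

    def test_uniform_beta_contributes_nothing(self):
        flat = PriorSpec(alpha_a=1.0, alpha_b=1.0)
        informative = PriorSpec(alpha_a=1.0, alpha_b=9.0)
        p = ModelParams(0.5, 2.0, 5.0)
        # same truncated-Gaussian parts, so the difference is the Beta term
        diff = log_prior(informative, p) - log_prior(flat, p)
        assert diff == pytest.approx(stats.beta.logpdf(0.5, 1, 9))

    def test_matches_scipy_densities(self, default_prior):
        p = ModelParams(0.5, 2.0, 5.0)
        expected = (
            stats.beta.logpdf(0.5, 1, 9)
            + stats.truncnorm.logpdf(2.0, -2.0 / 0.5, np.inf, loc=2.0, scale=0.5)
            + stats.truncnorm.logpdf(5.0, -5.0 / 2.0, np.inf, loc=5.0, scale=2.0)
        )
        assert log_prior(default_prior, p) == pytest.approx(expected, rel=1e-12)

    def test_invalid_hyperparameters_raise(self):
        with pytest.raises(ValueError):
            PriorSpec(sd_B=0.0)
        with pytest.raises(ValueError):
            PriorSpec(alpha_a=-1.0)


class TestLogPosteriorUnnorm:
    def test_additivity(self, toy_tray, default_prior):
        p = ModelParams(0.8, 1.5, 3.0)
        assert log_posterior_unnorm(default_prior, toy_tray, p) == pytest.approx(
            log_prior(default_prior, p) + log_likelihood(p, toy_tray)
        )

    def test_flat_prior_cancels_in_differences(self, toy_tray):
        flat = PriorSpec(alpha_a=1.0, alpha_b=1.0, sd_B=1e4, sd_C=1e4)
        p1 = ModelParams(0.8, 1.5, 3.0)
        p2 = ModelParams(0.7, 2.0, 4.0)
        post_diff = log_posterior_unnorm(flat, toy_tray, p1) - log_posterior_unnorm(
            flat, toy_tray, p2
        )
        lik_diff = log_likelihood(p1, toy_tray) - log_likelihood(p2, toy_tray)
        assert post_diff == pytest.approx(lik_diff, abs=1e-6)

    def test_outside_support_is_minus_inf(self, toy_tray, default_prior):
        bad = ModelParams(0.5, -2.0, 5.0, validate=False)
        assert log_posterior_unnorm(default_prior, toy_tray, bad) == -np.inf


# ---------------------------------------------------------------------------
# Dataset invariants
# ---------------------------------------------------------------------------

class TestEmergenceDataset:
    def test_rejects_unsorted_edges(self):
        with pytest.raises(ValueError):
            EmergenceDataset(edges=[0.0, 2.0, 2.0], counts=[1, 1], n_censored=0)

    def test_rejects_negative_counts_and_censored(self):
        with pytest.raises(ValueError):
            EmergenceDataset(edges=[0.0, 2.0], counts=[-1], n_censored=0)
        with pytest.raises(ValueError):
            EmergenceDataset(edges=[0.0, 2.0], counts=[1], n_censored=-2)

    def test_rejects_inconsistent_total(self):
        with pytest.raises(ValueError):
            EmergenceDataset(edges=[0.0, 2.0], counts=[3], n_censored=1, n_total=5)

    def test_derives_total(self):
        data = EmergenceDataset(edges=[0.0, 2.0, 4.0], counts=[3, 2], n_censored=1)
        assert data.n_total == 6
        assert data.n_emerged == 5

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(1.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            ModelParams(0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            ModelParams(0.5, 1.0, -1.0)
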