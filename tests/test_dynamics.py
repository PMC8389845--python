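import numpy as np
import pytest
from hypothesis import given, strategies as st

from fixchoice.data import PriorSpec
from fixchoice.dynamics import (PosteriorState, addm_increment_mean, bound_at,
                                posterior_moments, posterior_update_step,
                                utility, utility_threshold)
from fixchoice.params import BoundSpec


class TestPosteriorMoments:
    def test_no_data_returns_prior(self, prior):
        assert posterior_moments(prior, 4.0, 0) == (prior.mu_p, prior.sigma_p)

    def test_flat_prior_limit(self):
        """sigma_p -> inf: mu -> xbar and sigma_post -> sigma/sqrt(T)."""
        mu, sd = posterior_moments(PriorSpec(0.0, 1e6), 1.0, 4, 3.0)
        assert mu == pytest.approx(3.0, abs=1e-6)
        assert sd == pytest.approx(0.5, abs=1e-6)

    def test_grid_bayes_oracle(self):
        """Brute-force Bayes on a fine value grid agrees with the closed form."""
        grid = np.linspace(-20.0, 20.0, 200_001)
        post = np.exp(-0.5 * grid**2) * np.exp(-0.5 * (2.0 - grid)**2)
        post /= post.sum()
        mu_g = float((grid * post).sum())
        sd_g = float(np.sqrt(((grid - mu_g) ** 2 * post).sum()))
        mu, sd = posterior_moments(PriorSpec(0.0, 1.0), 1.0, 1, 2.0)
        assert mu == pytest.approx(mu_g, abs=1e-4)
        assert sd == pytest.approx(sd_g, abs=1e-4)

    def test_sigma_post_decreases_with_T(self, prior):
        sds = [posterior_moments(prior, 4.0, T, 1.0)[1] for T in range(6)]
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_invalid_sigma_rejected(self, prior):
        with pytest.raises(ValueError):
            posterior_moments(prior, -1.0, 1, 0.0)


class TestSequentialUpdate:
    @given(st.lists(st.floats(-8.0, 8.0), min_size=1, max_size=12),
           st.floats(0.5, 10.0), st.floats(0.5, 10.0))
    def test_batch_equals_sequential(self, xs, sigma, sigma_p):
        """Conjugacy: iterating single-measurement updates reproduces the
        batch posterior computed from the sample mean."""
        prior = PriorSpec(mu_p=1.0, sigma_p=sigma_p)
        state = PosteriorState(prior=prior, sigma=sigma)
        for x in xs:
            state = posterior_update_step(state, "left", x)
        mu_seq, sd_seq = state.moments("left")
        mu_b, sd_b = posterior_moments(prior, sigma, len(xs), float(np.mean(xs)))
        assert mu_seq == pytest.approx(mu_b, abs=1e-12, rel=1e-12)
        assert sd_seq == pytest.approx(sd_b, abs=1e-12, rel=1e-12)

    def test_equal_precision_first_update(self):
        """sigma == sigma_p: first posterior mean is the simple average."""
        prior = PriorSpec(mu_p=2.0, sigma_p=3.0)
        state = posterior_update_step(
            PosteriorState(prior=prior, sigma=3.0), "left", 6.0)
        mu, _ = state.moments("left")
        assert mu == pytest.approx((2.0 + 6.0) / 2)

    def test_items_independent(self, prior):
        state = PosteriorState(prior=prior, sigma=4.0)
        before = state.moments("right")
        state = posterior_update_step(state, "left", 5.0)
        assert state.moments("right") == before
        assert (state.T_right, state.S_right) == (0, 0.0)


class TestUtility:
    def test_A_zero_is_posterior_mean(self):
        assert utility(1.7, 0.4, 0.0) == 1.7

    def test_arithmetic(self):
        assert utility(2.0, 1.0, 2.0) == 0.0

    def test_monotone_in_sigma_post(self):
        us = [utility(1.0, s, 0.8) for s in (3.0, 2.0, 1.0, 0.5)]
        assert all(a < b for a, b in zip(us, us[1:]))

    def test_threshold_at_criterion_is_half(self):
        assert utility_threshold(1.5, 0.7, v_crit=1.5) == pytest.approx(0.5)

    def test_threshold_limit_is_one(self):
        assert utility_threshold(1e6, 1.0, 0.0) == pytest.approx(1.0)

    def test_aversive_item_devalued_by_sampling(self):
        """Flat-prior case: with xbar < 0 the threshold utility falls as T
        grows, so longer looking makes an aversive item less attractive."""
        prior = PriorSpec(0.0, 1e6)
        sigma, xbar = 2.0, -1.0
        us = []
        for T in (1, 4, 9, 16):
            mu, sd = posterior_moments(prior, sigma, T, xbar)
            us.append(utility_threshold(mu, sd, 0.0))
        assert all(a > b for a, b in zip(us, us[1:]))

    def test_ranking_agreement_with_mean_utility(self):
        """With A=0 and equal posterior sds, both utilities rank items alike."""
        sd = 0.8
        for mu_a, mu_b in [(1.0, 2.0), (0.3, -0.4), (-2.0, -1.0)]:
            lin = np.sign(utility(mu_a, sd, 0.0) - utility(mu_b, sd, 0.0))
            thr = np.sign(utility_threshold(mu_a, sd) - utility_threshold(mu_b, sd))
            assert lin == thr


class TestBound:
    def test_t_zero_gives_B0(self):
        b = BoundSpec(B0=2.5, k=3.0, lam=1000.0, collapsing=True)
        assert bound_at(0.0, b) == pytest.approx(2.5)

    @pytest.mark.parametrize("k", [0.5, 1.0, 4.0])
    def test_at_lambda_decay_is_1_over_e(self, k):
        b = BoundSpec(B0=2.0, k=k, lam=1500.0, collapsing=True)
        assert bound_at(1500.0, b) == pytest.approx(2.0 * np.exp(-1.0))

    def test_k1_is_exponential(self):
        b = BoundSpec(B0=1.0, k=1.0, lam=1000.0, collapsing=True)
        ts = np.array([0.0, 500.0, 1000.0, 2000.0])
        assert np.allclose(bound_at(ts, b), np.exp(-ts / 1000.0))

    def test_non_collapsing_constant(self):
        b = BoundSpec(B0=1.0, collapsing=False)
        assert bound_at(5000.0, b) == 1.0

    def test_non_increasing(self):
        b = BoundSpec(B0=1.0, k=2.3, lam=800.0, collapsing=True)
        ts = np.linspace(0, 5000, 200)
        vals = bound_at(ts, b)
        assert np.all(np.diff(vals) <= 1e-15)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bound_at(-1.0, BoundSpec(B0=1.0))


class TestADDMIncrement:
    def test_theta_one_symmetric(self):
        # theta=1 gives d*(r_l - r_r) regardless of the fixated side
        assert addm_increment_mean("left", 5.0, 3.0, 0.1, 1.0) == pytest.approx(0.2)
        assert addm_increment_mean("right", 5.0, 3.0, 0.1, 1.0) == pytest.approx(0.2)

    def test_arithmetic(self):
        assert addm_increment_mean("left", 5.0, 3.0, 0.1, 0.5) == pytest.approx(0.35)

    def test_equal_ratings_antisymmetric(self):
        r, d, theta = 4.0, 0.1, 0.3
        up = addm_increment_mean("left", r, r, d, theta)
        dn = addm_increment_mean("right", r, r, d, theta)
        assert up == pytest.approx(-dn)
        assert up == pytest.approx(d * r * (1 - theta))
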