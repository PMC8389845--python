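import numpy as np
import pytest

from fixchoice.data import PriorSpec, StepSchedule
from fixchoice.params import DDMParams, PUCParams
from fixchoice.propagate import (AbsorptionRecord, propagate_addm,
                                 propagate_addm_batch, propagate_puc,
                                 propagate_puc_batch)
from oracles import cdf_max_dev, mc_addm, mc_puc


def random_schedule(rng, min_steps=6, max_steps=24):
    n = int(rng.integers(min_steps, max_steps + 1))
    first = int(rng.integers(0, 2))
    # alternating runs of 1-6 steps, like real fixation series
    sides = []
    side = ["left", "right"][first]
    while len(sides) < n:
        run = int(rng.integers(1, 7))
        sides.extend([side] * run)
        side = "right" if side == "left" else "left"
    return StepSchedule(step_ms=100.0, sides=tuple(sides[:n]))


class TestRecordInvariants:
    def test_first_bin_is_zero(self, addm_params, alternating_schedule):
        rec = propagate_addm(alternating_schedule, addm_params, 5.0, 3.0)
        assert rec.p_left[0] == 0.0 and rec.p_right[0] == 0.0

    def test_bins_match_schedule_length(self, addm_params, alternating_schedule):
        rec = propagate_addm(alternating_schedule, addm_params, 5.0, 3.0)
        assert rec.n_bins == alternating_schedule.n_steps + 1

    def test_narrow_grid_rejected(self, addm_params, alternating_schedule):
        with pytest.raises(ValueError):
            propagate_addm(alternating_schedule, addm_params, 5.0, 3.0, span=0.9)


class TestConservation:
    def test_addm_random_draws(self, rng):
        for _ in range(25):
            p = DDMParams(sigma=float(rng.uniform(0.08, 0.3)),
                          d=float(rng.uniform(0.004, 0.02)),
                          theta=float(rng.uniform(0.0, 1.0)),
                          g=0.0, tau=0.0,
                          collapsing=bool(rng.integers(0, 2)),
                          k=float(rng.uniform(0.5, 4.0)),
                          lam=float(rng.uniform(500, 6000)))
            rec = propagate_addm(random_schedule(rng), p,
                                 float(rng.integers(-10, 11)),
                                 float(rng.integers(-10, 11)))
            assert rec.total_mass == pytest.approx(1.0, abs=1e-6)
            assert np.all(rec.p_left >= 0) and np.all(rec.p_right >= 0)

    def test_puc_random_draws(self, rng, prior):
        for _ in range(10):
            p = PUCParams(sigma=float(rng.uniform(8, 20)),
                          A=float(rng.uniform(-1, 1.5)),
                          prior=prior,
                          B0=float(rng.uniform(3, 9)),
                          k=float(rng.uniform(1, 3)),
                          lam=float(rng.uniform(1500, 5000)),
                          g=0.0, tau=0.0)
            rec = propagate_puc(random_schedule(rng, 4, 14), p,
                                float(rng.integers(-10, 11)),
                                float(rng.integers(-10, 11)), n_grid=61)
            assert rec.total_mass == pytest.approx(1.0, abs=1e-6)


class TestSymmetry:
    def test_addm_theta1_equal_ratings(self, alternating_schedule):
        p = DDMParams(sigma=0.18, d=0.012, theta=1.0, g=0.0, tau=0.0)
        rec = propagate_addm(alternating_schedule, p, 4.0, 4.0)
        assert np.abs(rec.p_left - rec.p_right).max() < 1e-8

    def test_puc_A0_ratings_at_prior_mean_any_schedule(self, prior):
        """A=0 with both ratings at mu_p: left/right absorption identical
        regardless of fixation imbalance (both bias channels neutralized)."""
        p = PUCParams(sigma=14.0, A=0.0, prior=prior, B0=5.0, k=2.0,
                      lam=3000.0, g=0.0, tau=0.0)
        sched = StepSchedule(step_ms=100.0,
                             sides=("left", "left", "left", "right") * 4)
        rec = propagate_puc(sched, p, prior.mu_p, prior.mu_p, n_grid=101)
        assert abs(rec.total_left - rec.total_right) < 1e-8

    def test_puc_uncertainty_channel_favors_fixated(self, prior):
        """A>0, equal ratings at mu_p, 3:1 left fixation -> more left choices."""
        p = PUCParams(sigma=14.0, A=0.8, prior=prior, B0=5.0, k=2.0,
                      lam=3000.0, g=0.0, tau=0.0)
        sched = StepSchedule(step_ms=100.0,
                             sides=("left", "left", "left", "right") * 4)
        rec = propagate_puc(sched, p, prior.mu_p, prior.mu_p, n_grid=101)
        assert rec.total_left > rec.total_right


class TestOracleAgreement:
    """Light per-module Monte-Carlo checks (the broader randomized sweep is
    in the acceptance suite)."""

    def test_addm_matches_monte_carlo(self, addm_params, rng):
        sides = random_schedule(rng, 12, 20).sides
        sched = StepSchedule(step_ms=100.0, sides=sides)
        rec = propagate_addm(sched, addm_params, 6.0, 2.0)
        n = 50_000
        p_up, p_dn, surv = mc_addm(addm_params, sides, 6.0, 2.0, n=n, rng=rng)
        se = 3.0 * np.sqrt(0.25 / n)
        assert rec.total_left == pytest.approx(p_up.sum(), abs=se)
        assert rec.total_right == pytest.approx(p_dn.sum(), abs=se)
        assert cdf_max_dev(rec, p_up, p_dn, n) < 1.0

    def test_puc_matches_monte_carlo(self, puc_params, rng):
        sides = random_schedule(rng, 10, 16).sides
        sched = StepSchedule(step_ms=100.0, sides=sides)
        rec = propagate_puc(sched, puc_params, 5.0, -1.0, n_grid=241)
        n = 50_000
        p_up, p_dn, surv = mc_puc(puc_params, sides, 5.0, -1.0, n=n, rng=rng)
        se = 3.0 * np.sqrt(0.25 / n)
        assert rec.total_left == pytest.approx(p_up.sum(), abs=se)
        assert rec.total_right == pytest.approx(p_dn.sum(), abs=se)
        assert cdf_max_dev(rec, p_up, p_dn, n) < 1.0


class TestRefinementAndReduction:
    def test_grid_refinement_stable(self, addm_params, puc_params,
                                    alternating_schedule):
        """Doubling grid resolution moves total choice probabilities < 1e-3."""
        a1 = propagate_addm(alternating_schedule, addm_params, 5.0, 3.0, n_grid=601)
        a2 = propagate_addm(alternating_schedule, addm_params, 5.0, 3.0, n_grid=1201)
        assert abs(a1.total_left - a2.total_left) < 1e-3
        p1 = propagate_puc(alternating_schedule, puc_params, 5.0, 3.0, n_grid=301)
        p2 = propagate_puc(alternating_schedule, puc_params, 5.0, 3.0, n_grid=601)
        assert abs(p1.total_left - p2.total_left) < 1e-3

    def test_acbddm_reduces_to_addm(self, alternating_schedule):
        """lambda far beyond the horizon with large k: the Weibull bound is
        indistinguishable from a fixed bound."""
        fixed = DDMParams(sigma=0.15, d=0.012, theta=0.5, g=0.0, tau=0.0)
        horizon = alternating_schedule.duration
        collapsing = DDMParams(sigma=0.15, d=0.012, theta=0.5, g=0.0, tau=0.0,
                               collapsing=True, k=10.0, lam=10.0 * horizon)
        ra = propagate_addm(alternating_schedule, fixed, 5.0, 3.0)
        rc = propagate_addm(alternating_schedule, collapsing, 5.0, 3.0)
        assert np.abs(ra.p_left - rc.p_left).max() < 1e-6
        assert np.abs(ra.p_right - rc.p_right).max() < 1e-6
        assert abs(ra.p_survive - rc.p_survive) < 1e-6


class TestBatchedConsistency:
    def test_batch_matches_single(self, addm_params, puc_params, rng):
        scheds = [random_schedule(rng, 4, 12) for _ in range(5)]
        codes = [s.side_codes() for s in scheds]
        ratings = rng.integers(-9, 10, size=(5, 2)).astype(float)
        batch = propagate_addm_batch(codes, addm_params, ratings)
        for i, s in enumerate(scheds):
            single = propagate_addm(s, addm_params, *ratings[i])
            assert np.allclose(batch[i].p_left, single.p_left, atol=1e-12)
        batch_p = propagate_puc_batch(codes, puc_params, ratings, n_grid=61)
        for i, s in enumerate(scheds):
            single = propagate_puc(s, puc_params, *ratings[i], n_grid=61)
            assert np.allclose(batch_p[i].p_left, single.p_left, atol=1e-12)
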