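import numpy as np
import pytest

from fixchoice.data import StepSchedule, read_subject_data, write_subject_data
from fixchoice.params import DDMParams, PUCParams
from fixchoice.propagate import propagate_addm
from fixchoice.simulate import (FixationSampler, predict_trial_ensemble,
                                simulate_trial)
from fixchoice.synth import SynthConfig, generate_synthetic_experiment
from conftest import make_trial


@pytest.fixture
def sampler(rng):
    pool = np.exp(rng.normal(np.log(400.0), 0.5, 300))
    return FixationSampler(duration_pool=pool)


class TestSimulateTrial:
    def test_unreachable_bound_gives_none(self, prior):
        p = PUCParams(sigma=14.0, A=0.5, prior=prior, B0=1e6, k=2.0,
                      lam=3000.0, g=0.0, tau=0.0)
        sched = StepSchedule(step_ms=100.0, sides=("left", "right") * 5)
        out = simulate_trial("puc", p, 3.0, 1.0, schedule=sched, rng=0)
        assert out.choice == "none"
        assert out.decision_time is None

    def test_pure_guessing_choice_frequency(self, addm_params, sampler):
        from dataclasses import replace
        p = replace(addm_params, g=1.0)
        rng = np.random.default_rng(7)
        n = 4000
        lefts = sum(simulate_trial("addm", p, 2.0, 1.0, sampler=sampler,
                                   rng=rng).choice == "left"
                    for _ in range(n))
        assert abs(lefts / n - 0.5) <= 3.0 * np.sqrt(0.25 / n)

    def test_uncertainty_bias_toward_fixated(self, prior):
        """A>0, equal ratings at the prior mean, left fixated 3x longer:
        the fixated item is chosen more than half the time."""
        p = PUCParams(sigma=14.0, A=0.8, prior=prior, B0=5.0, k=2.0,
                      lam=3000.0, g=0.0, tau=0.0)
        sched = StepSchedule(step_ms=100.0,
                             sides=("left", "left", "left", "right") * 6)
        rng = np.random.default_rng(11)
        n, lefts, decided = 3000, 0, 0
        for _ in range(n):
            o = simulate_trial("puc", p, prior.mu_p, prior.mu_p,
                               schedule=sched, rng=rng)
            if o.choice in ("left", "right"):
                decided += 1
                lefts += o.choice == "left"
        assert decided > 0.5 * n
        assert lefts / decided > 0.5 + 3.0 * np.sqrt(0.25 / decided)

    def test_total_time_is_decision_plus_tau(self, addm_params, sampler):
        out = simulate_trial("addm", addm_params, 9.0, -9.0, sampler=sampler,
                             rng=3)
        assert out.choice in ("left", "right")
        assert out.total_fixation_time == pytest.approx(
            out.decision_time + addm_params.tau)

    def test_generated_fixations_sum_to_total(self, addm_params, sampler):
        out = simulate_trial("addm", addm_params, 5.0, -5.0, sampler=sampler,
                             rng=5)
        assert out.fixations is not None
        assert sum(f.duration for f in out.fixations) == pytest.approx(
            out.total_fixation_time, abs=1e-9)


class TestEnsemble:
    def test_count_and_no_none_with_sampler(self, addm_params, sampler):
        trial = make_trial(rl=4.0, rr=-1.0)
        outs = predict_trial_ensemble("addm", addm_params, trial, sampler,
                                      n_reps=10, rng=1)
        assert len(outs) == 10
        assert all(o.choice in ("left", "right") for o in outs)

    def test_seed_reproducibility(self, addm_params, sampler):
        trial = make_trial()
        a = predict_trial_ensemble("addm", addm_params, trial, sampler,
                                   n_reps=10, rng=42)
        b = predict_trial_ensemble("addm", addm_params, trial, sampler,
                                   n_reps=10, rng=42)
        assert a == b

    def test_choice_rate_matches_propagator(self, addm_params, sampler):
        """With a long schedule (negligible survival), the simulated choice
        frequency converges to the propagated total choice probability."""
        from dataclasses import replace
        p = replace(addm_params, g=0.0, tau=0.0, collapsing=True,
                    k=2.0, lam=1500.0)
        sched = StepSchedule(step_ms=100.0, sides=("left", "right") * 20)
        rec = propagate_addm(sched, p, 5.0, 2.0)
        assert rec.p_survive < 1e-3
        rng = np.random.default_rng(9)
        n = 4000
        lefts = sum(simulate_trial("acbddm", p, 5.0, 2.0, schedule=sched,
                                   rng=rng).choice == "left"
                    for _ in range(n))
        se = np.sqrt(rec.total_left * (1 - rec.total_left) / n)
        assert lefts / n == pytest.approx(rec.total_left, abs=3 * se + rec.p_survive)


class TestGenerator:
    def test_shape_and_invariants(self):
        cfg = SynthConfig(n_subjects=2, trials_per_subject=10)
        ds, man = generate_synthetic_experiment(cfg, rng=5)
        assert len(ds) == 2
        assert all(d.n_trials == 10 for d in ds)
        assert set(man) == {d.subject_id for d in ds}
        for d in ds:
            for t in d.trials:  # container invariants were validated on build
                assert t.total_fixation_time == pytest.approx(
                    sum(f.duration for f in t.fixations), abs=1.0)

    def test_manifest_records_every_parameter(self):
        cfg = SynthConfig(n_subjects=1, trials_per_subject=8,
                          generating_model="acbddm")
        _, man = generate_synthetic_experiment(cfg, rng=5)
        entry = next(iter(man.values()))
        assert entry["model"] == "acbddm"
        for key in ("sigma", "d", "theta", "k", "lam", "g", "tau"):
            assert key in entry

    def test_deterministic_output_files(self, tmp_path):
        cfg = SynthConfig(n_subjects=2, trials_per_subject=6)
        for run in ("a", "b"):
            ds, _ = generate_synthetic_experiment(cfg, rng=99)
            write_subject_data(ds, tmp_path / f"t{run}.csv",
                               tmp_path / f"f{run}.csv")
        assert (tmp_path / "ta.csv").read_bytes() == (tmp_path / "tb.csv").read_bytes()
        assert (tmp_path / "fa.csv").read_bytes() == (tmp_path / "fb.csv").read_bytes()

    def test_round_trip_through_io(self, tmp_path):
        cfg = SynthConfig(n_subjects=2, trials_per_subject=6)
        ds, _ = generate_synthetic_experiment(cfg, rng=3)
        write_subject_data(ds, tmp_path / "t.csv", tmp_path / "f.csv")
        back = read_subject_data(tmp_path / "t.csv", tmp_path / "f.csv")
        assert back == ds

    def test_addm_theta1_no_fixation_effect(self):
        """theta=1 removes the attentional asymmetry: equal-rating trials
        split 50/50 regardless of fixation imbalance."""
        ranges = dict(sigma=(0.14, 0.16), d=(0.009, 0.011),
                      theta=(1.0 - 1e-9, 1.0), g=(0.0, 1e-9), tau=(0.0, 1e-9))
        cfg = SynthConfig(n_subjects=2, trials_per_subject=400,
                          generating_model="addm", param_ranges=ranges,
                          rating_dist="uniform_int", rating_scale=(-2.0, 2.0))
        ds, _ = generate_synthetic_experiment(cfg, rng=17)
        eq = [t for d in ds for t in d.trials
              if t.rating_left == t.rating_right]
        assert len(eq) > 80
        lefts = np.mean([t.choice == "left" for t in eq])
        assert abs(lefts - 0.5) <= 3.0 * np.sqrt(0.25 / len(eq))

    def test_puc_choice_tracks_fixation_advantage(self):
        """PUC with A>0: among equal-rating trials, choosing left correlates
        positively with the signed fixation-time advantage."""
        from scipy import stats as st
        ranges = dict(sigma=(12.0, 16.0), A=(0.5, 1.0), B0=(4.5, 7.0),
                      k=(1.5, 2.5), lam=(2500.0, 4500.0), g=(0.0, 1e-9),
                      tau=(0.0, 100.0))
        cfg = SynthConfig(n_subjects=4, trials_per_subject=500,
                          generating_model="puc", param_ranges=ranges)
        ds, _ = generate_synthetic_experiment(cfg, rng=23)
        adv, ch = [], []
        for d in ds:
            for t in d.trials:
                if t.rating_left == t.rating_right:
                    adv.append(t.fixation_advantage)
                    ch.append(1.0 if t.choice == "left" else 0.0)
        assert len(adv) > 50
        rho = st.spearmanr(adv, ch).statistic
        assert rho > 0.1
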