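import numpy as np
import pytest
from hypothesis import settings

from fixchoice.data import (FixationEpoch, PriorSpec, StepSchedule,
                            SubjectDataset, Trial)
from fixchoice.params import DDMParams, PUCParams

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def make_trial(trial_id=0, rl=3.0, rr=-2.0, durations=((("left", 400.0)),
               ("right", 350.0), ("left", 250.0)), choice="left"):
    fixes = tuple(FixationEpoch(side=s, duration=d) for s, d in durations)
    total = sum(f.duration for f in fixes)
    return Trial(trial_id=trial_id, rating_left=rl, rating_right=rr,
                 fixations=fixes, choice=choice, total_fixation_time=total)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def prior():
    return PriorSpec(mu_p=0.0, sigma_p=6.0)


@pytest.fixture
def puc_params(prior):
    return PUCParams(sigma=14.0, A=0.6, prior=prior, B0=6.0, k=2.0,
                     lam=3000.0, g=0.05, tau=100.0)


@pytest.fixture
def addm_params():
    return DDMParams(sigma=0.15, d=0.012, theta=0.5, g=0.05, tau=100.0)


@pytest.fixture
def acbddm_params():
    return DDMParams(sigma=0.14, d=0.010, theta=0.5, g=0.05, tau=100.0,
                     collapsing=True, k=2.0, lam=3500.0)


@pytest.fixture
def alternating_schedule():
    return StepSchedule(step_ms=100.0, sides=("left", "right") * 8)


@pytest.fixture
def tiny_dataset(rng):
    """A small hand-rolled subject for I/O and likelihood plumbing tests."""
    trials = []
    for i in range(12):
        rl, rr = rng.integers(-10, 11, 2).astype(float)
        n_fix = int(rng.integers(2, 6))
        sides = ["left", "right"] if rng.random() < 0.5 else ["right", "left"]
        durations = [(sides[j % 2], float(rng.uniform(150, 700)))
                     for j in range(n_fix)]
        fixes = tuple(FixationEpoch(side=s, duration=d) for s, d in durations)
        trials.append(Trial(
            trial_id=i, rating_left=rl, rating_right=rr, fixations=fixes,
            choice="left" if rng.random() < 0.5 else "right",
            total_fixation_time=sum(f.duration for f in fixes)))
    return SubjectDataset(subject_id="s01", trials=tuple(trials))
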