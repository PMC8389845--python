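"""Generative-mode simulation of all three models.

A simulated trial steps the chosen model forward on the 100 ms grid until the
decision variable reaches the (possibly collapsing) bound: the PUC observer
draws one value measurement per step for the fixated item and updates that
item's posterior; the DDM observer adds the attentional drift plus Gaussian
noise.  With probability g the trial is instead a guess -- a uniform random
choice at a response time drawn from the guess-time Weibull.

If the supplied fixation schedule runs out before absorption, continuation
fixations can be resampled from a pool of empirical durations (sides strictly
alternating); without a sampler the outcome is ``choice='none'``.  When no
schedule is given at all (pure generation), the realized fixation series --
the one the simulated observer actually experienced, truncated at the total
fixation time -- is returned with the outcome, so generated datasets carry
the fixations that produced their choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import FixationEpoch, StepSchedule, Trial, quantize_fixations
from .dynamics import addm_increment_mean, bound_at, posterior_precision
from .likelihood import GuessTimePMF
from .params import DDMParams, ModelParams, PUCParams
from .propagate import _puc_utilities

__all__ = ["FixationSampler", "SimOutcome", "simulate_trial",
           "predict_trial_ensemble", "default_guess_weibull",
           "DEFAULT_GUESS_SHAPE", "DEFAULT_GUESS_SCALE"]

# Defaults for the guess/response-time Weibull used when no subject-level fit
# is supplied: shape 1.15, scale 1900 ms give a median of ~1.4 s and a mean of
# ~1.9 s total fixation time.
DEFAULT_GUESS_SHAPE = 1.15
DEFAULT_GUESS_SCALE = 1900.0

_MAX_STEPS = 600  # 60 s hard horizon for continuation sampling


def default_guess_weibull(step_ms: float = 100.0, horizon_ms: float = 6000.0,
                          shape: float = DEFAULT_GUESS_SHAPE,
                          scale: float = DEFAULT_GUESS_SCALE) -> GuessTimePMF:
    """A configured (not fitted) guess-time distribution for generative use."""
    n_bins = int(np.floor(horizon_ms / step_ms))
    edges = np.arange(n_bins + 1) * step_ms
    cdf = stats.weibull_min.cdf(edges, shape, scale=scale)
    pmf = np.empty(n_bins + 1)
    pmf[:n_bins] = np.diff(cdf)
    pmf[n_bins] = 1.0 - cdf[-1]
    return GuessTimePMF(shape, scale, step_ms, pmf)


@dataclass(frozen=True)
class FixationSampler:
    """Resamples fixation durations (with replacement) from an empirical pool;
    sides strictly alternate after the first, which is left with probability
    ``first_side_prob_left``."""

    duration_pool: np.ndarray
    first_side_prob_left: float = 0.5

    def __post_init__(self) -> None:
        pool = np.asarray(self.duration_pool, float)
        if len(pool) == 0 or np.any(pool <= 0):
            raise ValueError("duration pool must be non-empty and positive")
        object.__setattr__(self, "duration_pool", pool)

    def first_side(self, rng: np.random.Generator) -> str:
        return "left" if rng.random() < self.first_side_prob_left else "right"

    def draw_duration(self, rng: np.random.Generator) -> float:
        return float(self.duration_pool[rng.integers(len(self.duration_pool))])


@dataclass(frozen=True)
class SimOutcome:
    """Result of one simulated trial.

    ``decision_time`` is the internal decision (absorption) time; the total
    fixation time additionally includes the non-decision time tau.  A trial
    whose schedule ran out without absorption (and without a sampler) has
    ``choice='none'`` and no decision time.  ``last_side`` is the side
    fixated during the step in which the decision fell.  ``fixations`` holds
    the realized fixation series when the trial was generated from a sampler
    without a pre-set schedule (None otherwise).
    """

    choice: str  # left | right | none
    decision_time: float | None  # ms
    total_fixation_time: float  # ms
    last_side: str | None = None
    guessed: bool = False
    fixations: tuple[FixationEpoch, ...] | None = None
    advantage_ms: float | None = None  # realized left-minus-right fixation time


class _FixationFeed:
    """Supplies fixated sides step by step and remembers the continuation
    epochs it draws, so the realized series can be reconstructed."""

    def __init__(self, schedule: StepSchedule | None,
                 sampler: FixationSampler | None,
                 step_ms: float, rng: np.random.Generator) -> None:
        self.schedule = schedule
        self.sampler = sampler
        self.step_ms = step_ms
        self.rng = rng
        self.drawn: list[tuple[str, float]] = []  # continuation epochs
        self._cum = 0.0
        self._steps_emitted = 0
        if schedule is not None:
            self._next_side = None  # decided when continuation starts
        else:
            self._next_side = sampler.first_side(rng) if sampler else None

    def _draw_epoch(self) -> None:
        side = self._next_side
        dur = self.sampler.draw_duration(self.rng)
        self.drawn.append((side, dur))
        self._cum += dur
        self._next_side = "right" if side == "left" else "left"

    def sides(self):
        n = 0
        if self.schedule is not None:
            for s in self.schedule.sides:
                yield s
                n += 1
            if self.sampler is None:
                return
            last = self.schedule.sides[-1]
            self._next_side = "right" if last == "left" else "left"
        elif self.sampler is None:
            return
        # continuation: cumulative quantization of freshly drawn epochs
        while n < _MAX_STEPS:
            upto = int(np.floor(self._cum / self.step_ms + 0.5))
            while self._steps_emitted >= upto:
                self._draw_epoch()
                upto = int(np.floor(self._cum / self.step_ms + 0.5))
            side = self.drawn[-1][0]
            # the side of the epoch covering this step under cumulative rounding
            cum = 0.0
            for sd, dur in self.drawn:
                cum += dur
                if int(np.floor(cum / self.step_ms + 0.5)) > self._steps_emitted:
                    side = sd
                    break
            yield side
            self._steps_emitted += 1
            n += 1

    def realized_fixations(self, total_ms: float) -> tuple[FixationEpoch, ...]:
        """The drawn series extended/truncated to sum exactly to total_ms.
        Only meaningful in pure-generation mode (no pre-set schedule)."""
        while self._cum < total_ms and self.sampler is not None:
            if self._next_side is None:
                self._next_side = self.sampler.first_side(self.rng)
            self._draw_epoch()
        out: list[FixationEpoch] = []
        cum = 0.0
        for side, dur in self.drawn:
            if cum + dur >= total_ms:
                if total_ms - cum > 0:
                    out.append(FixationEpoch(side=side, duration=total_ms - cum))
                break
            out.append(FixationEpoch(side=side, duration=dur))
            cum += dur
        return tuple(out)


def _sample_guess_time(guess: GuessTimePMF, tau: float, step_ms: float,
                       rng: np.random.Generator) -> float:
    """Total fixation time of a guess trial (kept above tau)."""
    if not np.isfinite(guess.weibull_shape):  # degenerate point mass
        return max(guess.weibull_scale, tau + step_ms)
    for _ in range(100):
        t = float(stats.weibull_min.rvs(guess.weibull_shape,
                                        scale=guess.weibull_scale,
                                        random_state=rng))
        if t > tau:
            return t
    return tau + step_ms


def simulate_trial(model: str, params: ModelParams, r_left: float, r_right: float,
                   schedule: StepSchedule | None = None,
                   sampler: FixationSampler | None = None,
                   rng: np.random.Generator | int | None = None,
                   guess: GuessTimePMF | None = None,
                   step_ms: float = 100.0) -> SimOutcome:
    """Simulate one trial of 'puc', 'addm' or 'acbddm'.

    Reproducible for a fixed ``rng`` seed.  Either a schedule, a sampler, or
    both must be given; with both, the sampler supplies continuation
    fixations after the schedule is exhausted.
    """
    if schedule is None and sampler is None:
        raise ValueError("need a schedule, a sampler, or both")
    if schedule is not None:
        step_ms = schedule.step_ms
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    feed = _FixationFeed(schedule, sampler, step_ms, rng)
    generated = schedule is None

    side_iter = feed.sides()
    sides_seen: list[str] = []

    def take(n: int) -> list[str]:
        while len(sides_seen) < n:
            try:
                sides_seen.append(next(side_iter))
            except StopIteration:
                break
        return sides_seen[:n]

    def advantage(total_ms: float) -> float:
        target = max(int(np.floor(total_ms / step_ms + 0.5)), 1)
        sd = take(target)
        return step_ms * sum(1.0 if x == "left" else -1.0 for x in sd)

    if params.g > 0 and rng.random() < params.g:
        if guess is None:
            guess = default_guess_weibull(step_ms)
        total = _sample_guess_time(guess, params.tau, step_ms, rng)
        choice = "left" if rng.random() < 0.5 else "right"
        dec = total - params.tau
        adv = advantage(total)
        fixes = feed.realized_fixations(total) if generated else None
        idx = min(max(int(np.ceil(dec / step_ms)) - 1, 0), len(sides_seen) - 1)
        last = sides_seen[idx] if sides_seen else None
        return SimOutcome(choice=choice, decision_time=dec,
                          total_fixation_time=total, last_side=last,
                          guessed=True, fixations=fixes, advantage_ms=adv)

    bspec = params.bound
    if model == "puc":
        assert isinstance(params, PUCParams)
        prior, sig = params.prior, params.sigma
        T = {"left": 0, "right": 0}
        S = {"left": 0.0, "right": 0.0}
        v = {"left": r_left, "right": r_right}
    else:
        assert isinstance(params, DDMParams)

    dv = 0.0
    s = 0
    while True:
        got = take(s + 1)
        if len(got) <= s:
            break
        side = got[s]
        s += 1
        if model == "puc":
            x = rng.normal(v[side], sig)
            T[side] += 1
            S[side] += x
            u = {}
            for it in ("left", "right"):
                kappa = posterior_precision(prior, sig, T[it])
                mu = (prior.mu_p / prior.sigma_p**2 + S[it] / sig**2) / kappa
                u[it] = float(_puc_utilities(np.asarray(mu), kappa**-0.5, params))
            dv = u["left"] - u["right"]
        else:
            dv += addm_increment_mean(side, r_left, r_right, params.d, params.theta)
            dv += rng.normal(0.0, params.sigma)
        b = bound_at(s * step_ms, bspec)
        if dv >= b or dv <= -b:
            dec = s * step_ms
            total = dec + params.tau
            adv = advantage(total)
            fixes = feed.realized_fixations(total) if generated else None
            return SimOutcome(choice="left" if dv >= b else "right",
                              decision_time=dec, total_fixation_time=total,
                              last_side=side, fixations=fixes, advantage_ms=adv)
    return SimOutcome(choice="none", decision_time=None,
                      total_fixation_time=s * step_ms, last_side=None)


def predict_trial_ensemble(model: str, params: ModelParams, trial: Trial,
                           sampler: FixationSampler, n_reps: int = 10,
                           rng: np.random.Generator | int | None = None,
                           guess: GuessTimePMF | None = None,
                           step_ms: float = 100.0) -> list[SimOutcome]:
    """n_reps simulations of one trial: the empirical schedule first, then
    sampler-drawn continuation fixations, so total fixation time is
    unrestricted.  Used to build model-predicted summary statistics."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    schedule = quantize_fixations(trial.fixations, step_ms)
    return [simulate_trial(model, params, trial.rating_left, trial.rating_right,
                           schedule=schedule, sampler=sampler, rng=rng,
                           guess=guess, step_ms=step_ms)
            for _ in range(n_reps)]
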