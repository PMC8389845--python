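"""Joint likelihood of (choice, total fixation time) per trial and per dataset.

Each trial's fixation series is quantized to the 100 ms step grid and the
decision-variable distribution is propagated along it (see ``propagate``).
The probability that the model produces the observed choice at the observed
total fixation time T_obs is the absorbed mass in the decision bin
``floor((T_obs - tau)/step)`` at the chosen bound; a bin beyond the modeled
horizon (or before step 1) contributes zero.  That model probability is mixed
with a guessing component: with probability g the choice is random (50/50)
and the response time is drawn from a subject-level Weibull fitted once to
the observed total fixation times.  The guessing mixture is the mechanism
that keeps the likelihood surface smooth and strictly positive; a hard floor
of 1e-300 guards the log.

The dataset log-likelihood is the sum of per-trial log probabilities, each
trial propagated with its own empirical fixation schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SubjectDataset, quantize_fixations
from .params import DDMParams, ModelParams, PUCParams
from .propagate import AbsorptionRecord, propagate_addm_batch, propagate_puc_batch

__all__ = ["GuessTimePMF", "TrialLikelihood", "fit_guess_time_pmf",
           "trial_loglik", "dataset_loglik", "LOG_FLOOR"]

LOG_FLOOR = np.log(1e-300)

MODELS = ("puc", "addm", "acbddm")


@dataclass(frozen=True)
class GuessTimePMF:
    """Binned guess-response-time distribution (Weibull fit, per subject).

    ``binned_pmf[b]`` is the probability of a guess response with total
    fixation time in ``[b*step, (b+1)*step)``; the final entry is the
    overflow bin beyond the maximum observed time.
    """

    weibull_shape: float
    weibull_scale: float  # ms
    step_ms: float
    binned_pmf: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "binned_pmf", np.asarray(self.binned_pmf, float))
        total = float(self.binned_pmf.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"guess pmf sums to {total}, not 1")

    def bin_index(self, t_ms: float) -> int:
        """Bin containing time t (clamped into the overflow bin)."""
        return min(int(np.floor(t_ms / self.step_ms)), len(self.binned_pmf) - 1)

    def prob(self, t_ms: float) -> float:
        return float(self.binned_pmf[self.bin_index(t_ms)])

    def to_dict(self) -> dict:
        return {"weibull_shape": self.weibull_shape,
                "weibull_scale": self.weibull_scale,
                "step_ms": self.step_ms,
                "binned_pmf": self.binned_pmf.tolist()}


def fit_guess_time_pmf(total_fixation_times, step_ms: float = 100.0) -> GuessTimePMF:
    """Maximum-likelihood Weibull fit to a subject's total fixation times,
    integrated over the step bins (plus one overflow bin).

    Fitted once per subject, before any model parameter is touched, so the
    guessing component of the likelihood is fixed during optimization.
    """
    t = np.asarray(total_fixation_times, float)
    if len(t) < 5:
        raise ValueError("need at least 5 observations to fit the guess-time Weibull")
    if np.any(t <= 0):
        raise ValueError("total fixation times must be positive")
    if np.ptp(t) == 0:
        warnings.warn("degenerate (constant) fixation times; using a point-mass "
                      "guess-time distribution", stacklevel=2)
        b = int(np.floor(t[0] / step_ms))
        pmf = np.zeros(b + 2)
        pmf[b] = 1.0
        return GuessTimePMF(np.inf, float(t[0]), step_ms, pmf)
    shape, _, scale = stats.weibull_min.fit(t, floc=0.0)
    n_bins = int(np.floor(t.max() / step_ms)) + 1
    edges = np.arange(n_bins + 1) * step_ms
    cdf = stats.weibull_min.cdf(edges, shape, scale=scale)
    pmf = np.empty(n_bins + 1)
    pmf[:n_bins] = np.diff(cdf)
    pmf[n_bins] = 1.0 - cdf[-1]  # overflow
    return GuessTimePMF(float(shape), float(scale), step_ms, pmf)


@dataclass(frozen=True)
class TrialLikelihood:
    """Per-trial likelihood decomposition: exp(log_p) = (1-g)*p_model + g*p_guess."""

    log_p: float
    p_model_component: float
    p_guess_component: float


def trial_loglik(absorption: AbsorptionRecord, choice: str, T_obs: float,
                 g: float, tau: float, guess: GuessTimePMF) -> TrialLikelihood:
    """Likelihood of one observed (choice, total fixation time) pair.

    The decision bin is ``floor((T_obs - tau)/step)``; the model observer is
    *not* constrained to decide at the end of the fixation series, so the bin
    may fall anywhere inside it (out-of-range bins get model probability 0).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if T_obs <= 0:
        raise ValueError("T_obs must be > 0")
    step = absorption.step_ms
    b = int(np.floor((T_obs - tau) / step))
    p_arr = absorption.p_choice(choice)
    p_model = float(p_arr[b]) if 0 <= b < len(p_arr) else 0.0
    p_guess = 0.5 * guess.prob(T_obs)
    p = (1.0 - g) * p_model + g * p_guess
    log_p = float(np.log(p)) if p > 1e-300 else LOG_FLOOR
    return TrialLikelihood(log_p=log_p, p_model_component=p_model,
                           p_guess_component=p_guess)


def _schedules_and_ratings(dataset: SubjectDataset, step_ms: float):
    codes, ratings = [], []
    for t in dataset.trials:
        codes.append(quantize_fixations(t.fixations, step_ms).side_codes())
        ratings.append((t.rating_left, t.rating_right))
    return codes, np.asarray(ratings, float)


def propagate_dataset(params: ModelParams, dataset: SubjectDataset, model: str,
                      step_ms: float = 100.0, n_grid: int | None = None,
                      span: float = 1.5) -> list[AbsorptionRecord]:
    """One AbsorptionRecord per trial, using each trial's empirical schedule."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    codes, ratings = _schedules_and_ratings(dataset, step_ms)
    if model == "puc":
        if not isinstance(params, PUCParams):
            raise TypeError("model 'puc' requires PUCParams")
        return propagate_puc_batch(codes, params, ratings, step_ms=step_ms,
                                   n_grid=n_grid or 301)
    if not isinstance(params, DDMParams):
        raise TypeError(f"model {model!r} requires DDMParams")
    if model == "addm" and params.collapsing:
        raise ValueError("model 'addm' uses a fixed bound; got collapsing params")
    if model == "acbddm" and not params.collapsing:
        raise ValueError("model 'acbddm' requires collapsing params")
    return propagate_addm_batch(codes, params, ratings, step_ms=step_ms,
                                n_grid=n_grid or 601, span=span)


def dataset_loglik(params: ModelParams, dataset: SubjectDataset, model: str,
                   guess: GuessTimePMF | None = None, step_ms: float = 100.0,
                   n_grid: int | None = None, verbose: bool = False) -> float:
    """Log-likelihood of the parameters on one subject's data (sum over trials)."""
    if guess is None:
        guess = fit_guess_time_pmf(dataset.total_fixation_times(), step_ms)
    try:
        records = propagate_dataset(params, dataset, model, step_ms=step_ms,
                                    n_grid=n_grid)
    except (TypeError, ValueError):
        raise  # caller errors (wrong params/model combination) pass through
    except Exception as err:  # pragma: no cover - defensive
        raise RuntimeError(f"propagation failed for subject "
                           f"{dataset.subject_id}: {err}") from err
    total = 0.0
    for trial, rec in zip(dataset.trials, records):
        tl = trial_loglik(rec, trial.choice, trial.total_fixation_time,
                          params.g, params.tau, guess)
        if verbose:
            b = int(np.floor((trial.total_fixation_time - params.tau) / step_ms))
            print(f"trial {trial.trial_id}: bin={b} p_model="
                  f"{tl.p_model_component:.3e} p_guess={tl.p_guess_component:.3e}")
        total += tl.log_p
    return total
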