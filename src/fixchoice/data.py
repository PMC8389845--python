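"""Trial-level data containers, delimited-text I/O and time discretization.

The experimental unit is a two-alternative food-choice trial: the subject has
previously rated both items on a bounded scale (default -10..10), then views
the two items through an alternating series of eye fixations and eventually
chooses one.  The models in this package consume, per trial, the two ratings,
the ordered fixation series (side, duration in ms), the choice, and the total
fixation time (the summed duration of all item fixations; saccade/transition
gaps are excluded upstream and never represented here).

All times are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FixationEpoch",
    "Trial",
    "SubjectDataset",
    "StepSchedule",
    "PriorSpec",
    "read_subject_data",
    "write_subject_data",
    "quantize_fixations",
    "empirical_prior",
]

SIDES = ("left", "right")

#: tolerance (ms) for total_fixation_time vs the summed fixation durations
_TOTAL_TIME_TOL = 1.0


class SchemaError(ValueError):
    """A data file does not conform to the declared column schema."""


class IntegrityError(ValueError):
    """Cross-record consistency violated (e.g. fixation with unknown trial)."""


def _check_side(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    return side


@dataclass(frozen=True)
class FixationEpoch:
    """One uninterrupted fixation on a single item."""

    side: str
    duration: float  # ms, strictly positive

    def __post_init__(self) -> None:
        _check_side(self.side)
        if not self.duration > 0:
            raise ValueError(f"fixation duration must be > 0 ms, got {self.duration}")


@dataclass(frozen=True)
class Trial:
    """A single binary choice trial.

    ``total_fixation_time`` must equal the summed fixation durations within
    1 ms; it is the quantity the models treat as the response time proxy.
    """

    trial_id: int
    rating_left: float
    rating_right: float
    fixations: tuple[FixationEpoch, ...]
    choice: str
    total_fixation_time: float  # ms

    def __post_init__(self) -> None:
        _check_side(self.choice)
        if len(self.fixations) == 0:
            raise ValueError(f"trial {self.trial_id}: fixation series is empty")
        object.__setattr__(self, "fixations", tuple(self.fixations))
        total = sum(f.duration for f in self.fixations)
        if abs(total - self.total_fixation_time) > _TOTAL_TIME_TOL:
            raise IntegrityError(
                f"trial {self.trial_id}: summed fixation durations {total:.3f} ms "
                f"differ from total_fixation_time {self.total_fixation_time:.3f} ms "
                f"by more than {_TOTAL_TIME_TOL} ms"
            )

    @property
    def rating_difference(self) -> float:
        return self.rating_left - self.rating_right

    @property
    def fixation_advantage(self) -> float:
        """Signed left-minus-right total fixation time (ms)."""
        adv = 0.0
        for f in self.fixations:
            adv += f.duration if f.side == "left" else -f.duration
        return adv

    @property
    def last_side(self) -> str:
        return self.fixations[-1].side


@dataclass(frozen=True)
class SubjectDataset:
    """All trials of one subject plus the rating-scale bounds."""

    subject_id: str
    trials: tuple[Trial, ...]
    rating_scale: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        if len(self.trials) == 0:
            raise ValueError(f"subject {self.subject_id}: no trials")
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"subject {self.subject_id}: duplicate trial ids")
        lo, hi = self.rating_scale
        for t in self.trials:
            for r in (t.rating_left, t.rating_right):
                if not (lo - 1e-9 <= r <= hi + 1e-9):
                    raise ValueError(
                        f"subject {self.subject_id} trial {t.trial_id}: rating {r} "
                        f"outside scale [{lo}, {hi}]"
                    )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def ratings(self) -> np.ndarray:
        """All item ratings of this subject (two per trial, pooled)."""
        out = np.empty(2 * len(self.trials))
        for i, t in enumerate(self.trials):
            out[2 * i] = t.rating_left
            out[2 * i + 1] = t.rating_right
        return out

    def total_fixation_times(self) -> np.ndarray:
        return np.array([t.total_fixation_time for t in self.trials])


@dataclass(frozen=True)
class StepSchedule:
    """Per-time-step fixated side on a uniform grid (default 100 ms)."""

    step_ms: float
    sides: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sides) == 0:
            raise ValueError("StepSchedule must have at least one step")
        for s in self.sides:
            _check_side(s)
        object.__setattr__(self, "sides", tuple(self.sides))

    @property
    def n_steps(self) -> int:
        return len(self.sides)

    @property
    def duration(self) -> float:
        return self.n_steps * self.step_ms

    def side_codes(self) -> np.ndarray:
        """0 for left, 1 for right, one entry per step."""
        return np.fromiter((0 if s == "left" else 1 for s in self.sides), int,
                           count=len(self.sides))


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior over item value: p(v) = N(v; mu_p, sigma_p^2)."""

    mu_p: float
    sigma_p: float

    def __post_init__(self) -> None:
        if not self.sigma_p > 0:
            raise ValueError(f"sigma_p must be > 0, got {self.sigma_p}")


# ---------------------------------------------------------------------------
# time discretization
# ---------------------------------------------------------------------------

def quantize_fixations(fixations: Sequence[FixationEpoch], step_ms: float = 100.0) -> StepSchedule:
    """Discretize a fixation series onto a uniform step grid.

    Uses cumulative rounding: the boundary after fixation j is placed at
    ``round(cum_duration_j / step_ms)`` steps, so the total step count is
    ``round(total / step_ms)`` and rounding error never accumulates across a
    long series.  A series shorter than half a step is promoted to one step.
    """
    if step_ms <= 0:
        raise ValueError("step_ms must be > 0")
    fixations = list(fixations)
    if not fixations:
        raise ValueError("empty fixation sequence")
    cum = np.cumsum([f.duration for f in fixations])
    # np.round would give banker's rounding; use floor(x+0.5) for the
    # conventional half-up boundary placement
    bounds = np.floor(cum / step_ms + 0.5).astype(int)
    sides: list[str] = []
    prev = 0
    for f, b in zip(fixations, bounds):
        sides.extend([f.side] * (b - prev))
        prev = max(prev, b)
    if not sides:  # promotion rule for very short series
        sides = [fixations[0].side]
    return StepSchedule(step_ms=step_ms, sides=tuple(sides))


# ---------------------------------------------------------------------------
# empirical prior
# ---------------------------------------------------------------------------

def empirical_prior(dataset: SubjectDataset, ddof: int = 1) -> PriorSpec:
    """Prior over value from the subject's own ratings.

    Pools both items of every trial; mu_p is the arithmetic mean and sigma_p
    the standard deviation (sample estimator, ``ddof=1``, by default).
    """
    ratings = dataset.ratings()
    sd = float(np.std(ratings, ddof=ddof))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError(
            f"subject {dataset.subject_id}: ratings have zero variance; "
            "cannot form an empirical prior"
        )
    return PriorSpec(mu_p=float(np.mean(ratings)), sigma_p=sd)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_TRIAL_COLS = ["subject_id", "trial_id", "rating_left", "rating_right",
               "choice", "total_fixation_time_ms"]
_FIX_COLS = ["subject_id", "trial_id", "fixation_index", "side", "duration_ms"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing so write -> read is bit-identical
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_subject_data(trials_path, fixations_path,
                      rating_scale: tuple[float, float] = (-10.0, 10.0),
                      ) -> list[SubjectDataset]:
    """Read trials + fixations files into one ``SubjectDataset`` per subject.

    Both files are delimited text (comma or tab, sniffed) with a header row;
    see the package docs for the column schema.  Fixations are attached to
    trials in ``fixation_index`` order and all container invariants are
    validated on construction.
    """
    trials_df = _read_table(trials_path, _TRIAL_COLS)
    fix_df = _read_table(fixations_path, _FIX_COLS)

    bad = fix_df["duration_ms"] <= 0
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{fixations_path}: non-positive duration_ms at row {row} "
            f"(value {fix_df['duration_ms'].iloc[row]})"
        )

    trial_keys = set(zip(trials_df["subject_id"].astype(str),
                         trials_df["trial_id"].astype(int)))
    fix_keys = set(zip(fix_df["subject_id"].astype(str),
                       fix_df["trial_id"].astype(int)))
    orphans = fix_keys - trial_keys
    if orphans:
        raise IntegrityError(
            f"{fixations_path}: fixations reference unknown trial(s): "
            f"{sorted(orphans)[:5]}"
        )

    fix_df = fix_df.sort_values(["subject_id", "trial_id", "fixation_index"])
    fix_groups = {k: g for k, g in fix_df.groupby(["subject_id", "trial_id"], sort=False)}

    datasets = []
    for sid, g in trials_df.groupby("subject_id", sort=True):
        trials = []
        for row in g.itertuples(index=False):
            key = (str(sid), int(row.trial_id))
            if key not in fix_groups:
                raise IntegrityError(
                    f"trial {row.trial_id} of subject {sid} has no fixations"
                )
            fg = fix_groups[key]
            fixes = tuple(FixationEpoch(side=str(s), duration=float(d))
                          for s, d in zip(fg["side"], fg["duration_ms"]))
            trials.append(Trial(
                trial_id=int(row.trial_id),
                rating_left=float(row.rating_left),
                rating_right=float(row.rating_right),
                fixations=fixes,
                choice=str(row.choice),
                total_fixation_time=float(row.total_fixation_time_ms),
            ))
        datasets.append(SubjectDataset(subject_id=str(sid), trials=tuple(trials),
                                       rating_scale=rating_scale))
    return datasets


def write_subject_data(datasets: Iterable[SubjectDataset], trials_path, fixations_path) -> None:
    """Write datasets to the two delimited-text files (comma-separated).

    Round-trips bit-identically through :func:`read_subject_data` at full
    float repr precision.
    """
    trial_rows, fix_rows = [], []
    for ds in datasets:
        for t in ds.trials:
            trial_rows.append((ds.subject_id, t.trial_id, t.rating_left,
                               t.rating_right, t.choice, t.total_fixation_time))
            for j, f in enumerate(t.fixations):
                fix_rows.append((ds.subject_id, t.trial_id, j, f.side, f.duration))
    pd.DataFrame(trial_rows, columns=_TRIAL_COLS).to_csv(trials_path, index=False)
    pd.DataFrame(fix_rows, columns=_FIX_COLS).to_csv(fixations_path, index=False)
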