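"""Behavioral summary statistics for observed or model-predicted trials.

All summaries operate on a flat records table (one row per trial or per
simulated prediction) with columns

    choice             'left' | 'right'
    advantage_ms       left-minus-right total fixation time
    rating_left, rating_right
    rating_diff        rating_left - rating_right
    last_side          side of the fixation containing the decision
    total_ms           total fixation time

built by :func:`records_from_dataset` or :func:`records_from_predictions`.
Aggregation is over individual trials (each simulated repetition counts as a
trial), never over rating pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SubjectDataset, Trial
from .simulate import SimOutcome

__all__ = ["SummaryCurve", "records_from_dataset", "records_from_predictions",
           "choice_vs_fixation_advantage", "choice_vs_advantage_by_rating",
           "last_fixation_effect", "fixation_time_distribution",
           "DEFAULT_ADVANTAGE_EDGES"]

DEFAULT_ADVANTAGE_EDGES = np.arange(-2000.0, 2001.0, 200.0)


@dataclass(frozen=True)
class SummaryCurve:
    """Binned proportion (or density) with per-bin counts.

    Empty bins have value NaN ("absent", not zero).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, int))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_lo": self.bin_edges[:-1],
                             "bin_hi": self.bin_edges[1:],
                             "value": self.values,
                             "count": self.counts,
                             "group": self.label})


def records_from_dataset(dataset: SubjectDataset) -> pd.DataFrame:
    """Records table from observed trials (last fixation = final epoch)."""
    rows = [{"choice": t.choice,
             "advantage_ms": t.fixation_advantage,
             "rating_left": t.rating_left,
             "rating_right": t.rating_right,
             "rating_diff": t.rating_difference,
             "last_side": t.last_side,
             "total_ms": t.total_fixation_time}
            for t in dataset.trials]
    return pd.DataFrame(rows)


def records_from_predictions(trial: Trial, outcomes: list[SimOutcome]) -> pd.DataFrame:
    """Records table from model predictions of one trial.

    Each simulated repetition contributes one row; the fixation advantage and
    last fixated side are the *realized* ones up to the simulated total
    fixation time (empirical schedule plus resampled continuation), so
    prediction-based curves have unrestricted response times.
    """
    rows = []
    for o in outcomes:
        if o.choice == "none":
            continue
        adv = o.advantage_ms if o.advantage_ms is not None else trial.fixation_advantage
        rows.append({"choice": o.choice,
                     "advantage_ms": adv,
                     "rating_left": trial.rating_left,
                     "rating_right": trial.rating_right,
                     "rating_diff": trial.rating_difference,
                     "last_side": o.last_side or trial.last_side,
                     "total_ms": o.total_fixation_time})
    return pd.DataFrame(rows)


def _prop_left(records: pd.DataFrame, by: np.ndarray,
               edges: np.ndarray, label: str = "") -> SummaryCurve:
    left = (records["choice"] == "left").to_numpy(float)
    idx = np.digitize(by, edges) - 1
    nb = len(edges) - 1
    values = np.full(nb, np.nan)
    counts = np.zeros(nb, int)
    for b in range(nb):
        m = idx == b
        counts[b] = int(m.sum())
        if counts[b]:
            values[b] = float(left[m].mean())
    return SummaryCurve(bin_edges=edges, values=values, counts=counts, label=label)


def choice_vs_fixation_advantage(records: pd.DataFrame,
                                 bin_edges: np.ndarray | None = None,
                                 label: str = "") -> SummaryCurve:
    """Proportion of left choices per bin of signed fixation-time advantage
    (left total minus right total, ms)."""
    edges = DEFAULT_ADVANTAGE_EDGES if bin_edges is None else np.asarray(bin_edges, float)
    return _prop_left(records, records["advantage_ms"].to_numpy(float), edges, label)


def choice_vs_advantage_by_rating(records: pd.DataFrame,
                                  bin_edges: np.ndarray | None = None,
                                  rating_groups: list[tuple[float, float]] | None = None,
                                  ) -> list[SummaryCurve]:
    """One advantage curve per group of mean item rating.

    ``rating_groups`` are half-open intervals [lo, hi) partitioning the mean
    of the two item ratings; higher-rating groups are predicted to show a
    steeper fixation-modulation effect.
    """
    if rating_groups is None:
        rating_groups = [(-10.0, 0.0), (0.0, 5.0), (5.0, 10.001)]
    mean_rating = 0.5 * (records["rating_left"] + records["rating_right"]).to_numpy(float)
    edges = DEFAULT_ADVANTAGE_EDGES if bin_edges is None else np.asarray(bin_edges, float)
    curves = []
    for lo, hi in rating_groups:
        sub = records[(mean_rating >= lo) & (mean_rating < hi)]
        curves.append(_prop_left(sub, sub["advantage_ms"].to_numpy(float),
                                 edges, label=f"[{lo},{hi})"))
    return curves


def last_fixation_effect(records: pd.DataFrame,
                         rating_diff_bins: np.ndarray | None = None,
                         ) -> tuple[SummaryCurve, SummaryCurve]:
    """Proportion of left choices vs rating difference, split by the side of
    the last fixation (the fixation containing the decision)."""
    edges = (np.arange(-10.5, 11.5, 1.0) if rating_diff_bins is None
             else np.asarray(rating_diff_bins, float))
    out = []
    for side in ("left", "right"):
        sub = records[records["last_side"] == side]
        out.append(_prop_left(sub, sub["rating_diff"].to_numpy(float),
                              edges, label=f"last={side}"))
    return out[0], out[1]


def fixation_time_distribution(records: pd.DataFrame,
                               bin_width_ms: float = 200.0) -> SummaryCurve:
    """Normalized histogram (density per ms) of total fixation times."""
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be > 0")
    t = records["total_ms"].to_numpy(float)
    hi = np.ceil(t.max() / bin_width_ms) * bin_width_ms if len(t) else bin_width_ms
    edges = np.arange(0.0, hi + bin_width_ms, bin_width_ms)
    counts, _ = np.histogram(t, bins=edges)
    dens = counts / max(counts.sum(), 1) / bin_width_ms
    return SummaryCurve(bin_edges=edges, values=dens, counts=counts,
                        label="total_fixation_time")
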