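"""Model/Results front end in the statsmodels idiom.

``FixationChoiceModel`` binds one subject's trial data to one of the three
decision models ('puc', 'addm', 'acbddm'); ``fit()`` runs the multi-start
maximum-likelihood machinery and returns a ``FixationChoiceResults`` carrying
the estimates, fit statistics and optimizer diagnostics, with ``summary()``,
``simulate()`` and prediction-based summary curves hanging off it.

Example
-------
>>> from fixchoice import FixationChoiceModel
>>> m = FixationChoiceModel(dataset, model="addm")
>>> res = m.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .data import SubjectDataset, read_subject_data
from .fitting import FitConfig, FitResult, fit_subject, free_parameter_names
from .likelihood import dataset_loglik
from .params import ModelParams
from .simulate import FixationSampler, predict_trial_ensemble
from .summaries import (SummaryCurve, choice_vs_fixation_advantage,
                        records_from_predictions)

__all__ = ["FixationChoiceModel", "FixationChoiceResults"]


class FixationChoiceModel:
    """A fixation-gated choice model bound to one subject's data."""

    def __init__(self, dataset: SubjectDataset, model: str = "puc",
                 config: FitConfig | None = None) -> None:
        if model not in ("puc", "addm", "acbddm"):
            raise ValueError(f"model must be 'puc', 'addm' or 'acbddm', got {model!r}")
        self.dataset = dataset
        self.model = model
        self.config = config or FitConfig()

    @classmethod
    def from_files(cls, trials_path, fixations_path, subject_id: str | None = None,
                   model: str = "puc", config: FitConfig | None = None,
                   ) -> "FixationChoiceModel":
        """Build from the delimited trials/fixations files (one subject)."""
        datasets = read_subject_data(trials_path, fixations_path)
        if subject_id is None:
            if len(datasets) != 1:
                raise ValueError("multiple subjects in file; pass subject_id")
            ds = datasets[0]
        else:
            by_id = {d.subject_id: d for d in datasets}
            ds = by_id[str(subject_id)]
        return cls(ds, model=model, config=config)

    def loglike(self, params: ModelParams) -> float:
        """Dataset log-likelihood at the given parameters."""
        n_grid = self.config.puc_grid if self.model == "puc" else self.config.addm_grid
        return dataset_loglik(params, self.dataset, self.model,
                              step_ms=self.config.step_ms, n_grid=n_grid)

    def fit(self, config: FitConfig | None = None) -> "FixationChoiceResults":
        fr = fit_subject(self.dataset, self.model, config or self.config)
        return FixationChoiceResults(self, fr)


class FixationChoiceResults:
    """MLE results for one subject; wraps :class:`fixchoice.fitting.FitResult`."""

    def __init__(self, model: FixationChoiceModel, fit_result: FitResult) -> None:
        self.model_obj = model
        self.fit_result = fit_result

    # -- statsmodels-style accessors ------------------------------------
    @property
    def params(self) -> dict[str, float]:
        names = free_parameter_names(self.fit_result.model,
                                     self.model_obj.config)
        return {n: getattr(self.fit_result.params_hat, n) for n in names}

    @property
    def params_object(self) -> ModelParams:
        return self.fit_result.params_hat

    @property
    def llf(self) -> float:
        return self.fit_result.loglik

    @property
    def aicc(self) -> float:
        return self.fit_result.aicc

    @property
    def bic(self) -> float:
        return self.fit_result.bic

    @property
    def nobs(self) -> int:
        return self.fit_result.n_trials

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            "Fixation-gated choice model results",
            "=" * 43,
            f"subject:        {fr.subject_id}",
            f"model:          {fr.model}",
            f"n trials:       {fr.n_trials}",
            f"free params:    {fr.n_free_params}",
            f"log-likelihood: {fr.loglik:.3f}",
            f"AICc:           {fr.aicc:.3f}",
            f"BIC:            {fr.bic:.3f}",
            "-" * 43,
        ]
        for name, val in self.params.items():
            lines.append(f"{name:10s} {val:12.5g}")
        n_conv = sum(1 for s in fr.starts if s.converged)
        lines.append("-" * 43)
        lines.append(f"starts: {len(fr.starts)} ({n_conv} converged); "
                     f"best start loglik {max(s.final_value for s in fr.starts):.3f}")
        return "\n".join(lines)

    # -- simulation ------------------------------------------------------
    def simulate(self, n_reps: int = 10,
                 rng: np.random.Generator | int | None = None) -> pd.DataFrame:
        """Model-predicted records for every trial (continuation-resampled)."""
        ds = self.model_obj.dataset
        pool = np.concatenate([[f.duration for f in t.fixations]
                               for t in ds.trials])
        sampler = FixationSampler(duration_pool=pool)
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        frames = []
        for t in ds.trials:
            outs = predict_trial_ensemble(self.fit_result.model,
                                          self.fit_result.params_hat, t,
                                          sampler, n_reps=n_reps, rng=rng)
            frames.append(records_from_predictions(t, outs))
        return pd.concat(frames, ignore_index=True)

    def predicted_choice_curve(self, n_reps: int = 10,
                               rng: np.random.Generator | int | None = None,
                               ) -> SummaryCurve:
        return choice_vs_fixation_advantage(self.simulate(n_reps=n_reps, rng=rng))

    def to_dict(self) -> dict:
        fr = self.fit_result
        d = asdict(fr.params_hat)
        return {"subject_id": fr.subject_id, "model": fr.model,
                "params": d, "loglik": fr.loglik, "aicc": fr.aicc,
                "bic": fr.bic, "n_free_params": fr.n_free_params,
                "n_trials": fr.n_trials}
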