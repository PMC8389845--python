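"""Per-subject maximum-likelihood fitting and information criteria.

Fitting maximizes the dataset log-likelihood over a box-constrained parameter
space, reparametrized onto the unit cube (log-spaced coordinates for positive
scale parameters, shifted-log for the non-decision time, linear for the
rest).  The two nuisance parameters that do not enter the propagation -- the
lapse rate g and the non-decision time tau -- are profiled out exactly: for
each tau candidate on a fine grid the decision bins are fixed and g solves a
1-D concave problem, so evaluating the profile costs a vectorized pass over
the cached absorption records.  The outer search over the propagation
parameters is two-phase: a Latin-hypercube screening pool is evaluated once,
and bounded Nelder-Mead local optimization (with simplex restarts) runs from
the best ``n_starts`` screening points.  Derivative-free search is deliberate
(the surface has plateaus and soft ridges), and the screening phase avoids
the broad spurious basin in which the model component is negligible and the
guessing mixture absorbs everything.

Free-parameter counts follow the "equal parameter count" comparison logic:
PUC 7 (sigma, A, B0, k, lam, g, tau; the prior is fixed empirically),
acbDDM 7 (sigma, d, theta, k, lam, g, tau; bound height fixed at 1),
aDDM 5 (sigma, d, theta, g, tau).  The PUC variants toggle A / free the
prior moments and adjust the count accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .data import SubjectDataset, empirical_prior
from .likelihood import _schedules_and_ratings, fit_guess_time_pmf
from .propagate import propagate_addm_batch, propagate_puc_batch
from .params import DDMParams, ModelParams, PUCParams

__all__ = ["FitConfig", "FitResult", "fit_subject", "information_criteria",
           "free_parameter_names", "params_from_vector"]

_TAU_EPS = 10.0  # ms shift for the log transform of tau

# (low, high, scale); scale in {"log", "linear", "log_eps"}
DEFAULT_BOUNDS: dict[str, tuple[float, float, str]] = {
    "sigma": (0.01, 20.0, "log"),
    "A": (-10.0, 10.0, "linear"),
    "B0": (0.1, 100.0, "log"),
    "k": (0.2, 10.0, "log"),
    "lam": (100.0, 20000.0, "log"),
    "g": (1e-4, 0.5, "log"),
    "tau": (0.0, 1000.0, "log_eps"),
    "d": (1e-4, 5.0, "log"),
    "theta": (0.0, 1.0, "linear"),
    "sigma_p": (0.1, 20.0, "log"),
    "mu_p": (-10.0, 10.0, "linear"),
}


@dataclass(frozen=True)
class FitConfig:
    """Multi-start optimization settings.

    bounds entries override :data:`DEFAULT_BOUNDS` per parameter; grid sizes
    control the propagation resolution used inside the likelihood.
    """

    n_starts: int = 20
    n_screen: int = 64
    nm_restarts: int = 3
    bounds: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    xtol: float = 1e-3
    maxfev: int | None = None
    rng_seed: int | None = None
    step_ms: float = 100.0
    addm_grid: int = 601
    puc_grid: int = 301
    free_prior_sigma: bool = False
    free_prior_mean: bool = False
    zero_A: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def bound_for(self, name: str) -> tuple[float, float, str]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


def free_parameter_names(model: str, config: FitConfig) -> list[str]:
    if model == "puc":
        names = ["sigma", "A", "B0", "k", "lam", "g", "tau"]
        if config.zero_A:
            names.remove("A")
        if config.free_prior_sigma or config.free_prior_mean:
            names.append("sigma_p")
        if config.free_prior_mean:
            names.append("mu_p")
        return names
    if model == "addm":
        return ["sigma", "d", "theta", "g", "tau"]
    if model == "acbddm":
        return ["sigma", "d", "theta", "k", "lam", "g", "tau"]
    raise ValueError(f"unknown model {model!r}")


def _from_unit(u: float, lo: float, hi: float, scale: str) -> float:
    if scale == "log":
        return lo * (hi / lo) ** u
    if scale == "log_eps":
        return (lo + _TAU_EPS) * ((hi + _TAU_EPS) / (lo + _TAU_EPS)) ** u - _TAU_EPS
    return lo + (hi - lo) * u


def _to_unit(p: float, lo: float, hi: float, scale: str) -> float:
    if scale == "log":
        return math.log(p / lo) / math.log(hi / lo)
    if scale == "log_eps":
        return math.log((p + _TAU_EPS) / (lo + _TAU_EPS)) / \
            math.log((hi + _TAU_EPS) / (lo + _TAU_EPS))
    return (p - lo) / (hi - lo)


def params_from_vector(u: np.ndarray, model: str, config: FitConfig,
                       dataset: SubjectDataset) -> ModelParams:
    """Map a unit-cube vector to a full parameter object (fixed fields filled)."""
    names = free_parameter_names(model, config)
    vals = {n: _from_unit(float(ui), *config.bound_for(n))
            for n, ui in zip(names, u)}
    if model == "puc":
        prior = empirical_prior(dataset)
        if "sigma_p" in vals or "mu_p" in vals:
            prior = type(prior)(mu_p=vals.pop("mu_p", prior.mu_p),
                                sigma_p=vals.pop("sigma_p", prior.sigma_p))
        if config.zero_A:
            vals["A"] = 0.0
        return PUCParams(prior=prior, zero_A=config.zero_A,
                         free_prior_sigma=config.free_prior_sigma,
                         free_prior_mean=config.free_prior_mean, **vals)
    return DDMParams(collapsing=(model == "acbddm"), **vals)


def information_criteria(loglik: float, n_free: int, n_trials: int) -> tuple[float, float]:
    """Small-sample-corrected AIC and BIC.

        AICc = -2 ln L + 2k + 2k(k+1)/(n-k-1)
        BIC  = -2 ln L + k ln n

    with k free parameters and n trials (the independent units of the
    likelihood sum).
    """
    k, n = n_free, n_trials
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    bic = -2.0 * loglik + k * math.log(n)
    return aicc, bic


@dataclass(frozen=True)
class StartDiagnostic:
    start_unit: tuple[float, ...]
    start_value: float      # loglik at the start point
    final_value: float      # loglik at convergence
    n_evals: int
    converged: bool


@dataclass(frozen=True)
class FitResult:
    """MLE outcome for one subject under one model."""

    subject_id: str
    model: str
    params_hat: ModelParams
    loglik: float
    n_free_params: int
    n_trials: int
    aicc: float
    bic: float
    starts: tuple[StartDiagnostic, ...] = ()

    def __post_init__(self) -> None:
        aicc, bic = information_criteria(self.loglik, self.n_free_params,
                                         self.n_trials)
        if abs(aicc - self.aicc) > 1e-8 or abs(bic - self.bic) > 1e-8:
            raise ValueError("aicc/bic inconsistent with loglik and counts")


def fit_subject(dataset: SubjectDataset, model: str,
                config: FitConfig | None = None) -> FitResult:
    """Maximum-likelihood fit of one model to one subject.

    Deterministic for a fixed ``config.rng_seed``.
    """
    config = config or FitConfig()
    names = free_parameter_names(model, config)
    k = len(names)
    guess = fit_guess_time_pmf(dataset.total_fixation_times(), config.step_ms)
    n_grid = config.puc_grid if model == "puc" else config.addm_grid

    # g and tau do not enter the propagation, so they are profiled out of
    # the search: for each candidate tau on a fine grid the decision bins
    # are fixed, and the lapse rate g then solves a 1-D concave problem
    # (golden section).  The outer optimizer only sees the propagation
    # parameters, which removes the tau plateaus from its surface.
    outer = [n for n in names if n not in ("g", "tau")]
    k_out = len(outer)
    g_lo, g_hi, _ = config.bound_for("g")
    tau_lo, tau_hi, _ = config.bound_for("tau")
    tau_grid = np.arange(tau_lo, tau_hi + 1e-9, 10.0)

    # fixed per-trial quantities for the vectorized likelihood assembly
    codes, rmat = _schedules_and_ratings(dataset, config.step_ms)
    t_obs = dataset.total_fixation_times()
    p_guess = 0.5 * np.array([guess.prob(t) for t in t_obs])
    choices = [t.choice for t in dataset.trials]
    # decision bin per (tau candidate, trial)
    bins_ct = np.floor((t_obs[None, :] - tau_grid[:, None]) / config.step_ms
                       ).astype(int)

    def _pack(records) -> tuple[np.ndarray, np.ndarray]:
        """Absorption mass at the observed choice's bound, padded (n, S+1)."""
        lens = np.array([rec.n_bins for rec in records])
        P = np.zeros((len(records), int(lens.max())))
        for i, rec in enumerate(records):
            P[i, :lens[i]] = rec.p_choice(choices[i])
        return P, lens

    def _profile_g_tau(P: np.ndarray, lens: np.ndarray):
        """Maximize the log-likelihood over (g, tau) for fixed propagation."""
        valid = (bins_ct >= 0) & (bins_ct < lens[None, :])
        pm = np.where(valid,
                      P[np.arange(len(lens))[None, :],
                        np.clip(bins_ct, 0, P.shape[1] - 1)],
                      0.0)                      # (C, n) model component
        lo = np.full(len(tau_grid), g_lo)
        hi = np.full(len(tau_grid), g_hi)
        phi = 0.5 * (np.sqrt(5.0) - 1.0)

        def ll_at(gv):
            p = (1.0 - gv[:, None]) * pm + gv[:, None] * p_guess[None, :]
            return np.log(np.maximum(p, 1e-300)).sum(axis=1)

        for _ in range(18):
            m1 = hi - phi * (hi - lo)
            m2 = lo + phi * (hi - lo)
            swap = ll_at(m1) > ll_at(m2)
            hi = np.where(swap, m2, hi)
            lo = np.where(swap, lo, m1)
        g_star = 0.5 * (lo + hi)
        ll = ll_at(g_star)
        c = int(np.argmax(ll))
        return float(ll[c]), float(g_star[c]), float(tau_grid[c])

    prop_cache: dict[tuple, tuple] = {}

    def _outer_params(u: np.ndarray) -> dict:
        u = np.clip(u, 1e-9, 1 - 1e-9)
        return {n: _from_unit(float(ui), *config.bound_for(n))
                for n, ui in zip(outer, u)}

    def _build_params(vals: dict, g: float, tau: float) -> ModelParams:
        full = dict(vals, g=g, tau=tau)
        if model == "puc":
            prior = empirical_prior(dataset)
            if "sigma_p" in full or "mu_p" in full:
                prior = type(prior)(mu_p=full.pop("mu_p", prior.mu_p),
                                    sigma_p=full.pop("sigma_p", prior.sigma_p))
            if config.zero_A:
                full["A"] = 0.0
            return PUCParams(prior=prior, zero_A=config.zero_A,
                             free_prior_sigma=config.free_prior_sigma,
                             free_prior_mean=config.free_prior_mean, **full)
        return DDMParams(collapsing=(model == "acbddm"), **full)

    def _evaluate(u: np.ndarray):
        vals = _outer_params(u)
        key = tuple(sorted(vals.items()))
        hit = prop_cache.get(key)
        if hit is None:
            params = _build_params(vals, 0.0, 0.0)
            if model == "puc":
                records = propagate_puc_batch(codes, params, rmat,
                                              step_ms=config.step_ms,
                                              n_grid=n_grid)
            else:
                records = propagate_addm_batch(codes, params, rmat,
                                               step_ms=config.step_ms,
                                               n_grid=n_grid)
            P, lens = _pack(records)
            hit = _profile_g_tau(P, lens)
            if len(prop_cache) > 16:
                prop_cache.clear()
            prop_cache[key] = hit
        return hit

    def negloglik(u: np.ndarray) -> float:
        return -_evaluate(u)[0]

    sampler = qmc.LatinHypercube(d=k_out, seed=config.rng_seed)
    pool = sampler.random(max(config.n_screen, config.n_starts))
    pool_vals = np.array([negloglik(u) for u in pool])
    order = np.argsort(pool_vals)
    starts = pool[order[:config.n_starts]]
    start_vals = pool_vals[order[:config.n_starts]]

    def _local(u0: np.ndarray):
        """Nelder-Mead with restarts (fresh simplex at the previous optimum,
        which reliably escapes degenerate simplices)."""
        u, val, nfev, ok = u0, np.inf, 0, False
        for _ in range(config.nm_restarts):
            res = optimize.minimize(
                negloglik, u, method="Nelder-Mead",
                bounds=[(0.0, 1.0)] * k_out,
                options={"xatol": config.xtol, "fatol": config.xtol,
                         "adaptive": True,
                         **({"maxfev": config.maxfev} if config.maxfev else {})})
            nfev += int(res.nfev)
            ok = bool(res.success)
            if res.fun >= val - config.xtol:
                u, val = (res.x, res.fun) if res.fun < val else (u, val)
                break
            u, val = res.x, res.fun
        return u, float(val), nfev, ok

    diagnostics = []
    best_u, best_val = None, np.inf
    for u0, f0 in zip(starts, start_vals):
        try:
            u_fin, val, nfev, ok = _local(u0)
        except Exception:
            diagnostics.append(StartDiagnostic(tuple(u0), -f0, -np.inf, 0, False))
            continue
        if f0 < val:
            u_fin, val = u0, f0
        diagnostics.append(StartDiagnostic(tuple(u0), -f0, -float(val), nfev, ok))
        if val < best_val:
            best_val, best_u = val, u_fin
    if best_u is None:
        raise RuntimeError(
            f"all {config.n_starts} optimization starts failed for subject "
            f"{dataset.subject_id} / {model}: {diagnostics}")

    ll_best, g_star, tau_star = _evaluate(best_u)
    params_hat = _build_params(_outer_params(best_u), g_star, tau_star)
    loglik = float(ll_best)
    aicc, bic = information_criteria(loglik, k, dataset.n_trials)
    return FitResult(subject_id=dataset.subject_id, model=model,
                     params_hat=params_hat, loglik=loglik, n_free_params=k,
                     n_trials=dataset.n_trials, aicc=aicc, bic=bic,
                     starts=tuple(diagnostics))
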