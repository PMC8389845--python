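"""Elementary model dynamics.

PUC side: conjugate-Gaussian posterior updating of each item's value belief,
the uncertainty-averse utility U = mu_post - A*sigma_post (and the optional
threshold utility P(v > v_crit)), and the Weibull collapsing bound.

DDM side: the deterministic part of the attentional drift increment; the
diffusion noise is added by the propagation / simulation layer.

All of these are closed-form scalars; they exist as named functions because
they are the vocabulary the propagators, simulators and tests share.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr

from .data import PriorSpec
from .params import BoundSpec

__all__ = [
    "posterior_moments",
    "posterior_precision",
    "update_coefficients",
    "PosteriorState",
    "posterior_update_step",
    "utility",
    "utility_threshold",
    "bound_at",
    "addm_increment_mean",
]


def posterior_precision(prior: PriorSpec, sigma: float, T) -> np.ndarray | float:
    """kappa_T = 1/sigma_p^2 + T/sigma^2 (posterior precision after T measurements)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return 1.0 / prior.sigma_p**2 + np.asarray(T, float) / sigma**2


def posterior_moments(prior: PriorSpec, sigma: float, T: int, xbar: float = 0.0):
    """Posterior mean and sd of an item's value after T measurements with mean xbar.

        mu_post    = (mu_p/sigma_p^2 + T*xbar/sigma^2) / kappa_T
        sigma_post = kappa_T**-0.5

    With T = 0 this returns the prior moments (xbar is ignored).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    kappa = posterior_precision(prior, sigma, T)
    if T == 0:
        return prior.mu_p, prior.sigma_p
    mu = (prior.mu_p / prior.sigma_p**2 + T * xbar / sigma**2) / kappa
    return float(mu), float(kappa**-0.5)


def update_coefficients(prior: PriorSpec, sigma: float, T: int) -> tuple[float, float]:
    """(alpha, beta) of the one-measurement recursion mu_new = alpha*mu + beta*x.

    alpha = kappa_T / kappa_{T+1}, beta = (1/sigma^2) / kappa_{T+1}; note
    alpha + beta = 1, i.e. the posterior mean is a precision-weighted average
    of the old mean and the new measurement.
    """
    k_t = posterior_precision(prior, sigma, T)
    k_t1 = k_t + 1.0 / sigma**2
    return float(k_t / k_t1), float((1.0 / sigma**2) / k_t1)


@dataclass(frozen=True)
class PosteriorState:
    """Per-item sufficient statistics of the two value posteriors."""

    prior: PriorSpec
    sigma: float
    T_left: int = 0
    S_left: float = 0.0
    T_right: int = 0
    S_right: float = 0.0

    def moments(self, item: str) -> tuple[float, float]:
        T = self.T_left if item == "left" else self.T_right
        S = self.S_left if item == "left" else self.S_right
        xbar = S / T if T > 0 else 0.0
        return posterior_moments(self.prior, self.sigma, T, xbar)


def posterior_update_step(state: PosteriorState, item: str, x: float) -> PosteriorState:
    """Absorb one measurement x of the given item; the other item is untouched."""
    if item == "left":
        return replace(state, T_left=state.T_left + 1, S_left=state.S_left + x)
    if item == "right":
        return replace(state, T_right=state.T_right + 1, S_right=state.S_right + x)
    raise ValueError(f"item must be 'left' or 'right', got {item!r}")


def utility(mu_post, sigma_post, A: float):
    """Uncertainty-averse utility: posterior mean minus A times posterior sd."""
    return mu_post - A * np.asarray(sigma_post)


def utility_threshold(mu_post, sigma_post, v_crit: float = 0.0):
    """P(v > v_crit) under the Gaussian posterior: Phi((mu_post - v_crit)/sigma_post).

    In the flat-prior limit with v_crit = 0 this reduces to
    Phi(xbar * sqrt(T) / sigma), so an aversive item (xbar < 0) becomes *less*
    attractive with more measurements.
    """
    sigma_post = np.asarray(sigma_post, float)
    if np.any(sigma_post <= 0):
        raise ValueError("sigma_post must be > 0")
    return ndtr((np.asarray(mu_post, float) - v_crit) / sigma_post)


def bound_at(t, bound: BoundSpec):
    """Bound height at time t (ms): B0*exp(-(t/lam)^k) if collapsing, else B0."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not bound.collapsing:
        return np.broadcast_to(np.asarray(bound.B0), t.shape).copy() if t.ndim else bound.B0
    out = bound.B0 * np.exp(-((t / bound.lam) ** bound.k))
    return float(out) if out.ndim == 0 else out


def addm_increment_mean(side: str, r_left: float, r_right: float,
                        d: float, theta: float) -> float:
    """Deterministic drift of the aDDM decision variable for one step.

    Fixating left:  d * (r_left - theta * r_right)
    Fixating right: d * (theta * r_left - r_right)

    The zero-mean Gaussian diffusion term is added by the caller.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    if side == "left":
        return d * (r_left - theta * r_right)
    if side == "right":
        return d * (theta * r_left - r_right)
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")
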