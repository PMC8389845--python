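"""Numerical propagation of the decision-variable distribution.

Both model families decide when a scalar decision variable (DV) first reaches
a symmetric (possibly collapsing) bound.  The joint probability of (choice,
decision step) is obtained by discrete-time Chapman-Kolmogorov propagation of
the DV distribution on a fixed grid: at each 100 ms step the density is pushed
through that step's transition kernel, and the mass at or beyond the two
bounds is removed and accumulated as the probability of responding in that
bin.  Surviving mass is carried forward *unnormalized*; whatever remains after
the final step of the fixation series is the probability of a later decision.

aDDM / acbDDM: the DV itself is Markov, so propagation is 1-D.  Each step
shifts the density by the attentional drift for the currently fixated side
and convolves it with a zero-mean Gaussian of sd ``sigma``; the shift and
noise are combined into a single cell-integrated kernel applied by FFT.

PUC: the scalar DV (the utility difference) is *not* Markov -- the minimal
Markov state is the pair of posterior means (mu_L, mu_R), because each item's
posterior mean contracts toward its own running average at an item-specific
rate.  Propagation therefore runs on a 2-D grid over (mu_L, mu_R).  A step
that measures item i applies, along that item's axis only, the affine
contraction mu -> alpha*mu followed by convolution with a Gaussian of mean
beta*v_i and sd beta*sigma (alpha, beta as in the conjugate one-measurement
recursion; v_i is the item's rating).  The posterior sds are deterministic
functions of the measurement counts, so the utility difference is a known
function on the grid at every step and absorption is a mask over grid cells.

Both propagators conserve probability exactly (up to float rounding): the
outermost target cells of every transition kernel integrate to +/-infinity,
and out-of-grid convolution mass is clamped to the edge cells (which for the
DDMs always lie beyond the bound and are absorbed the same step).

Batched variants propagate all trials of a subject simultaneously; they are
what makes maximum-likelihood fitting affordable and are used by the
likelihood layer.  The public single-trial functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len
from scipy.special import ndtr

from .data import StepSchedule
from .dynamics import bound_at, posterior_precision, utility, utility_threshold
from .params import DDMParams, PUCParams

__all__ = ["AbsorptionRecord", "propagate_addm", "propagate_puc",
           "propagate_addm_batch", "propagate_puc_batch"]


def _uniform_sf(t, width):
    """P(U >= t) for U uniform on [-width/2, width/2] (fractional absorption
    of a 1-D cell cut by a bound)."""
    return np.clip(0.5 - t / np.maximum(width, 1e-300), 0.0, 1.0)


def _trapezoid_sf(t, a, b):
    """P(U_a + U_b >= t) for independent uniforms on [-a/2,a/2], [-b/2,b/2].

    This is the exact fraction of a rectangular (a x b) cell lying beyond the
    line x - y = t, i.e. the sub-cell mass absorbed when a linear decision
    variable cuts through the cell.  Piecewise quadratic with a flat-top
    trapezoid density; degenerates to a step when a, b -> 0.
    """
    a = np.maximum(np.asarray(a, float), 1e-12)
    b = np.maximum(np.asarray(b, float), 1e-12)
    s = 0.5 * (a + b)
    r = 0.5 * np.abs(a - b)
    big = np.maximum(a, b)
    quad_hi = (s - t) ** 2 / (2.0 * a * b)     # r <= t < s
    quad_lo = 1.0 - (s + t) ** 2 / (2.0 * a * b)  # -s < t <= -r
    flat = 0.5 - t / big                        # |t| < r
    out = np.where(t >= s, 0.0,
                   np.where(t <= -s, 1.0,
                            np.where(t >= r, quad_hi,
                                     np.where(t <= -r, quad_lo, flat))))
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class AbsorptionRecord:
    """First-passage probabilities per time bin for one trial.

    ``p_left[s]`` (resp. ``p_right``) is the probability that the DV first
    crosses the upper (lower) bound at the end of step ``s`` (decision time
    ``s * step_ms``); index 0 is always 0 because no boundary check precedes
    the first step.  ``p_survive`` is the mass still inside the bounds after
    the final modeled step -- the single bin for all later decision times.
    """

    step_ms: float
    p_left: np.ndarray
    p_right: np.ndarray
    p_survive: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_left", np.asarray(self.p_left, float))
        object.__setattr__(self, "p_right", np.asarray(self.p_right, float))

    @property
    def n_bins(self) -> int:
        return len(self.p_left)

    @property
    def total_left(self) -> float:
        return float(self.p_left.sum())

    @property
    def total_right(self) -> float:
        return float(self.p_right.sum())

    @property
    def total_mass(self) -> float:
        return self.total_left + self.total_right + self.p_survive

    def p_choice(self, choice: str) -> np.ndarray:
        return self.p_left if choice == "left" else self.p_right

    def to_dict(self) -> dict:
        return {"step_ms": self.step_ms, "p_left": self.p_left.tolist(),
                "p_right": self.p_right.tolist(), "p_survive": self.p_survive}


def _as_side_codes(schedule: StepSchedule) -> np.ndarray:
    return schedule.side_codes()


# ---------------------------------------------------------------------------
# aDDM / acbDDM: 1-D FFT propagation
# ---------------------------------------------------------------------------

def propagate_addm_batch(side_codes: list[np.ndarray], params: DDMParams,
                         ratings: np.ndarray, step_ms: float = 100.0,
                         n_grid: int = 601, span: float = 1.5,
                         ) -> list[AbsorptionRecord]:
    """Propagate every trial of a subject at once.

    side_codes : per trial, int array of fixated sides (0=left, 1=right)
    ratings    : (n_trials, 2) array of (r_left, r_right)

    Returns one :class:`AbsorptionRecord` per trial.
    """
    if span <= 1.0:
        raise ValueError("grid span must exceed the bound height B0=1")
    if n_grid % 2 == 0:
        n_grid += 1  # keep 0 as an exact grid point
    n = len(side_codes)
    ratings = np.asarray(ratings, float).reshape(n, 2)
    lens = np.array([len(c) for c in side_codes], int)
    if np.any(lens < 1):
        raise ValueError("every schedule must have at least one step")
    S = int(lens.max())
    sides = np.zeros((n, S), int)
    for i, c in enumerate(side_codes):
        sides[i, :len(c)] = c

    N = n_grid
    x = np.linspace(-span, span, N)
    dx = x[1] - x[0]

    # per-trial drift for each fixated side
    mu = np.empty((n, 2))
    mu[:, 0] = params.d * (ratings[:, 0] - params.theta * ratings[:, 1])
    mu[:, 1] = params.d * (params.theta * ratings[:, 0] - ratings[:, 1])

    # cell-integrated transition kernels over offsets (m-(N-1))*dx
    offsets = (np.arange(2 * N - 1) - (N - 1)) * dx
    edges = np.concatenate(([-np.inf], offsets[:-1] + dx / 2, [np.inf]))
    cdf = ndtr((edges[None, None, :] - mu[:, :, None]) / params.sigma)
    kern = np.diff(cdf, axis=2)  # (n, 2, 2N-1), rows sum to 1 exactly

    M = next_fast_len(3 * N - 2)
    kern_f = np.fft.rfft(kern, M, axis=2)

    # sort trials by descending schedule length so the still-active set at
    # every step is the contiguous prefix [0:m) -- views instead of copies
    order = np.argsort(-lens, kind="stable")
    lens_s = lens[order]
    sides_s = sides[order]
    kern_f = kern_f[order]

    dens = np.zeros((n, N))
    dens[:, (N - 1) // 2] = 1.0  # point mass at DV=0

    p_up = np.zeros((n, S + 1))
    p_dn = np.zeros((n, S + 1))
    survive = np.zeros(n)
    bspec = params.bound
    rows = np.arange(n)
    pad = np.zeros((n, M - N))

    for s in range(1, S + 1):
        m = int(np.searchsorted(-lens_s, -s, side="right"))
        d_f = np.fft.rfft(np.concatenate([dens[:m], pad[:m]], axis=1), axis=1)
        d_f *= kern_f[rows[:m], sides_s[:m, s - 1]]
        conv = np.fft.irfft(d_f, M, axis=1)
        new = conv[:, N - 1:2 * N - 1]
        # clamp out-of-grid mass to the edge cells (beyond the bound, so it
        # is absorbed immediately below)
        new[:, 0] += conv[:, :N - 1].sum(axis=1)
        new[:, -1] += conv[:, 2 * N - 1:3 * N - 2].sum(axis=1)
        np.clip(new, 0.0, None, out=new)

        b = bound_at(s * step_ms, bspec)
        w_up = _uniform_sf(b - x, dx)
        w_dn = _uniform_sf(x + b, dx)
        tot = w_up + w_dn
        over = tot > 1.0
        if np.any(over):  # bound narrower than a cell
            w_up = np.where(over, w_up / tot, w_up)
            w_dn = np.where(over, w_dn / tot, w_dn)
        p_up[:m, s] = new @ w_up
        p_dn[:m, s] = new @ w_dn
        new *= 1.0 - w_up - w_dn
        dens[:m] = new

        first_done = int(np.searchsorted(-lens_s, -s, side="left"))
        if first_done < m:
            survive[first_done:m] = dens[first_done:m].sum(axis=1)

    inv = np.empty(n, int)
    inv[order] = np.arange(n)
    return [AbsorptionRecord(step_ms=step_ms,
                             p_left=p_up[inv[i], :lens[i] + 1],
                             p_right=p_dn[inv[i], :lens[i] + 1],
                             p_survive=float(survive[inv[i]]))
            for i in range(n)]


def propagate_addm(schedule: StepSchedule, params: DDMParams,
                   r_left: float, r_right: float,
                   n_grid: int = 601, span: float = 1.5) -> AbsorptionRecord:
    """Choice/decision-time probabilities for one aDDM or acbDDM trial."""
    return propagate_addm_batch([_as_side_codes(schedule)], params,
                                np.array([[r_left, r_right]]),
                                step_ms=schedule.step_ms,
                                n_grid=n_grid, span=span)[0]


# ---------------------------------------------------------------------------
# PUC: 2-D propagation over the posterior means
# ---------------------------------------------------------------------------

def _puc_axis(mu_p: float, sigma_p: float, r: float, n: int) -> np.ndarray:
    """Axis of n cell centers covering [min(mu_p,r)-4sd, max(mu_p,r)+4sd]
    with mu_p exactly on a grid point (the pre-measurement delta location).

    The posterior mean lives between the prior mean and the rating with
    marginal spread below sigma_p, so a 4-sigma_p buffer keeps edge clamping
    below ~1e-4 while keeping the cells fine."""
    lo = min(mu_p, r) - 4.0 * sigma_p
    hi = max(mu_p, r) + 4.0 * sigma_p
    dx = (hi - lo) / (n - 1)
    shift = (mu_p - lo) % dx
    return lo + shift + dx * np.arange(n)


def _puc_utilities(x: np.ndarray, sd: np.ndarray, params: PUCParams) -> np.ndarray:
    """Utility on the grid of posterior means; sd broadcasts per trial."""
    if params.utility == "threshold":
        return utility_threshold(x, sd, params.v_crit)
    return utility(x, sd, params.A)


def propagate_puc_batch(side_codes: list[np.ndarray], params: PUCParams,
                        ratings: np.ndarray, step_ms: float = 100.0,
                        n_grid: int = 301) -> list[AbsorptionRecord]:
    """Batched 2-D propagation of the PUC posterior-mean distribution."""
    n = len(side_codes)
    ratings = np.asarray(ratings, float).reshape(n, 2)
    lens = np.array([len(c) for c in side_codes], int)
    if np.any(lens < 1):
        raise ValueError("every schedule must have at least one step")
    S = int(lens.max())
    sides = np.zeros((n, S), int)
    for i, c in enumerate(side_codes):
        sides[i, :len(c)] = c
    # measurement counts of each item *after* step s (1-indexed)
    is_right = sides == 1
    TR_after = np.cumsum(is_right, axis=1)
    TL_after = np.cumsum(~is_right, axis=1)

    prior, sig = params.prior, params.sigma
    N = n_grid
    xL = np.empty((n, N))
    xR = np.empty((n, N))
    for i in range(n):
        xL[i] = _puc_axis(prior.mu_p, prior.sigma_p, ratings[i, 0], N)
        xR[i] = _puc_axis(prior.mu_p, prior.sigma_p, ratings[i, 1], N)
    iL0 = np.argmin(np.abs(xL - prior.mu_p), axis=1)
    iR0 = np.argmin(np.abs(xR - prior.mu_p), axis=1)

    dens = np.zeros((n, N, N))
    dens[np.arange(n), iL0, iR0] = 1.0

    p_up = np.zeros((n, S + 1))
    p_dn = np.zeros((n, S + 1))
    survive = np.zeros(n)
    active = np.ones(n, bool)
    bspec = params.bound

    # transition matrices depend only on (axis == rating, count); ratings
    # repeat across trials, so cache per (rating, T) within this call
    _tmat_cache: dict[tuple[float, int], np.ndarray] = {}

    def _transition_one(axis_x: np.ndarray, T_before: int, v: float) -> np.ndarray:
        key = (float(v), int(T_before))
        hit = _tmat_cache.get(key)
        if hit is not None:
            return hit
        k_t = posterior_precision(prior, sig, T_before)
        k_t1 = k_t + 1.0 / sig**2
        alpha = k_t / k_t1
        beta = (1.0 / sig**2) / k_t1
        m = alpha * axis_x + beta * v                    # (N,) kernel means
        s_k = beta * sig                                 # kernel sd
        dxs = axis_x[1] - axis_x[0]
        edges = np.concatenate(([-np.inf], axis_x[:-1] + 0.5 * dxs, [np.inf]))
        cdf = ndtr((edges[:, None] - m[None, :]) / s_k)
        out = np.diff(cdf, axis=0)                       # [target, source]
        _tmat_cache[key] = out
        return out

    def _transition(axis_x: np.ndarray, T_before: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.stack([_transition_one(axis_x[i], T_before[i], v[i])
                         for i in range(len(v))])

    for s in range(1, S + 1):
        idx = np.flatnonzero(active)
        upd_L = idx[sides[idx, s - 1] == 0]
        upd_R = idx[sides[idx, s - 1] == 1]
        if len(upd_L):
            M = _transition(xL[upd_L], TL_after[upd_L, s - 1] - 1, ratings[upd_L, 0])
            dens[upd_L] = np.matmul(M, dens[upd_L])
        if len(upd_R):
            M = _transition(xR[upd_R], TR_after[upd_R, s - 1] - 1, ratings[upd_R, 1])
            dens[upd_R] = np.matmul(dens[upd_R], M.transpose(0, 2, 1))

        sdL = posterior_precision(prior, sig, TL_after[idx, s - 1]) ** -0.5
        sdR = posterior_precision(prior, sig, TR_after[idx, s - 1]) ** -0.5
        uL = _puc_utilities(xL[idx], sdL[:, None], params)   # (B, N)
        uR = _puc_utilities(xR[idx], sdR[:, None], params)
        dv = uL[:, :, None] - uR[:, None, :]
        # per-cell DV extent along each axis (constant dx for the linear
        # utility; varies across cells for the threshold utility); an axis
        # still in its pre-measurement delta phase has zero extent
        aL = np.abs(np.gradient(uL, axis=1))[:, :, None] * \
            (TL_after[idx, s - 1] > 0)[:, None, None]
        aR = np.abs(np.gradient(uR, axis=1))[:, None, :] * \
            (TR_after[idx, s - 1] > 0)[:, None, None]
        b = bound_at(s * step_ms, bspec)
        w_up = _trapezoid_sf(b - dv, aL, aR)
        w_dn = _trapezoid_sf(b + dv, aL, aR)
        tot = w_up + w_dn
        over = tot > 1.0
        if np.any(over):  # bound narrower than a cell's DV extent
            w_up = np.where(over, w_up / tot, w_up)
            w_dn = np.where(over, w_dn / tot, w_dn)
        d_act = dens[idx]
        p_up[idx, s] = (d_act * w_up).sum(axis=(1, 2))
        p_dn[idx, s] = (d_act * w_dn).sum(axis=(1, 2))
        d_act *= 1.0 - w_up - w_dn
        dens[idx] = d_act

        done = idx[lens[idx] == s]
        survive[done] = dens[done].sum(axis=(1, 2))
        active[done] = False

    return [AbsorptionRecord(step_ms=step_ms,
                             p_left=p_up[i, :lens[i] + 1],
                             p_right=p_dn[i, :lens[i] + 1],
                             p_survive=float(survive[i]))
            for i in range(n)]


def propagate_puc(schedule: StepSchedule, params: PUCParams,
                  r_left: float, r_right: float,
                  n_grid: int = 301) -> AbsorptionRecord:
    """Choice/decision-time probabilities for one PUC trial."""
    return propagate_puc_batch([_as_side_codes(schedule)], params,
                               np.array([[r_left, r_right]]),
                               step_ms=schedule.step_ms, n_grid=n_grid)[0]
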