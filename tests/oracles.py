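"""Independent Monte-Carlo oracles for the propagators.

These simulate the step dynamics directly on vectorized replicate arrays and
never touch the density-propagation code paths they are used to check.
"""

import numpy as np

from fixchoice.dynamics import bound_at


def mc_addm(params, sides, r_left, r_right, n=100_000, rng=None, step_ms=100.0):
    """First-passage probabilities per bin for the attentional DDM."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dv = np.zeros(n)
    alive = np.ones(n, bool)
    p_up = np.zeros(len(sides) + 1)
    p_dn = np.zeros(len(sides) + 1)
    for s, side in enumerate(sides, 1):
        mu = params.d * ((r_left - params.theta * r_right) if side == "left"
                         else (params.theta * r_left - r_right))
        dv[alive] += mu + rng.normal(0.0, params.sigma, int(alive.sum()))
        b = bound_at(s * step_ms, params.bound)
        up = alive & (dv >= b)
        dn = alive & (dv <= -b)
        p_up[s] = up.mean()
        p_dn[s] = dn.mean()
        alive &= ~(up | dn)
    return p_up, p_dn, alive.mean()


def mc_puc(params, sides, r_left, r_right, n=100_000, rng=None, step_ms=100.0):
    """First-passage probabilities per bin for the posterior-utility model:
    sample one value measurement per step for the fixated item, update the
    conjugate posterior, and threshold the utility difference."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    prior, sig, A = params.prior, params.sigma, params.A
    k0 = 1.0 / prior.sigma_p**2
    TL = np.zeros(n)
    TR = np.zeros(n)
    SL = np.zeros(n)
    SR = np.zeros(n)
    alive = np.ones(n, bool)
    p_up = np.zeros(len(sides) + 1)
    p_dn = np.zeros(len(sides) + 1)
    for s, side in enumerate(sides, 1):
        x = rng.normal(r_left if side == "left" else r_right, sig, n)
        if side == "left":
            TL += alive
            SL += np.where(alive, x, 0.0)
        else:
            TR += alive
            SR += np.where(alive, x, 0.0)
        kL = k0 + TL / sig**2
        kR = k0 + TR / sig**2
        muL = (prior.mu_p * k0 + SL / sig**2) / kL
        muR = (prior.mu_p * k0 + SR / sig**2) / kR
        dv = (muL - A * kL**-0.5) - (muR - A * kR**-0.5)
        b = bound_at(s * step_ms, params.bound)
        up = alive & (dv >= b)
        dn = alive & (dv <= -b)
        p_up[s] = up.mean()
        p_dn[s] = dn.mean()
        alive &= ~(up | dn)
    return p_up, p_dn, alive.mean()


def cdf_max_dev(rec, p_up, p_dn, n):
    """Max deviation between propagated and Monte-Carlo decision-time CDFs,
    in units of its binomial 3-SE allowance (plus a small-count floor)."""
    f_prop = np.cumsum(rec.p_left + rec.p_right)
    f_mc = np.cumsum(p_up + p_dn)
    se = np.sqrt(np.maximum(f_prop * (1.0 - f_prop), 0.0) / n)
    allow = 3.0 * se + 5.0 / n
    return float(np.max(np.abs(f_prop - f_mc) / allow))
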