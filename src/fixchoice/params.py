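"""Parameter containers for the PUC and drift-diffusion models.

Conventions:

* all times (``lam``, ``tau``) in milliseconds;
* ``sigma`` is per 100 ms step (one measurement / one diffusion increment per
  step) in rating units for PUC and in bound units for the DDMs;
* the DDM bound height is fixed at 1 (only its shape parameters are free),
  while PUC carries an explicit ``B0`` because its scale is set by the
  ratings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Union

from .data import PriorSpec

__all__ = ["PUCParams", "DDMParams", "BoundSpec", "ModelParams",
           "params_to_json", "params_from_json"]


@dataclass(frozen=True)
class BoundSpec:
    """Decision bound B(t) = B0 * exp(-(t/lam)^k), or constant B0."""

    B0: float
    k: float = 1.0
    lam: float = 1000.0  # ms
    collapsing: bool = True

    def __post_init__(self) -> None:
        if not self.B0 > 0:
            raise ValueError("B0 must be > 0")
        if self.collapsing and not (self.k > 0 and self.lam > 0):
            raise ValueError("k and lam must be > 0 for a collapsing bound")


@dataclass(frozen=True)
class PUCParams:
    """Posterior-utility-choice model parameters.

    sigma : measurement noise (rating units, per step)
    A     : uncertainty-aversion weight on the posterior standard deviation
    prior : Gaussian prior over item value (usually the empirical prior)
    B0,k,lam : Weibull collapsing bound (B0 in rating units, lam in ms)
    g     : guessing (lapse) probability
    tau   : non-decision time (ms) -- post-decision looking time
    utility : "mean_minus_sd" (default) or "threshold" (P(v > v_crit))
    """

    sigma: float
    A: float
    prior: PriorSpec
    B0: float
    k: float
    lam: float
    g: float
    tau: float
    free_prior_sigma: bool = False
    free_prior_mean: bool = False
    zero_A: bool = False
    utility: str = "mean_minus_sd"
    v_crit: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma", "B0", "k", "lam"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.g <= 1.0):
            raise ValueError("g must lie in [0, 1]")
        if not self.tau >= 0:
            raise ValueError("tau must be >= 0")
        if self.zero_A and self.A != 0.0:
            raise ValueError("zero_A variant requires A == 0")
        if self.utility not in ("mean_minus_sd", "threshold"):
            raise ValueError(f"unknown utility {self.utility!r}")

    @property
    def bound(self) -> BoundSpec:
        return BoundSpec(B0=self.B0, k=self.k, lam=self.lam, collapsing=True)


@dataclass(frozen=True)
class DDMParams:
    """aDDM / acbDDM parameters (bound height fixed at 1).

    sigma : diffusion noise sd per step
    d     : drift scaling (bound units per rating unit per step)
    theta : attentional discount of the unfixated item's rating, in [0, 1]
    collapsing : False = fixed-bound aDDM, True = acbDDM with Weibull bound
    k, lam : bound shape/timescale, used only when collapsing
    g, tau : guessing rate and non-decision time, as in PUC
    """

    sigma: float
    d: float
    theta: float
    g: float
    tau: float
    collapsing: bool = False
    k: float = 1.0
    lam: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("sigma", "d", "k", "lam"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
        if not (0.0 <= self.g <= 1.0):
            raise ValueError("g must lie in [0, 1]")
        if not self.tau >= 0:
            raise ValueError("tau must be >= 0")

    @property
    def bound(self) -> BoundSpec:
        return BoundSpec(B0=1.0, k=self.k, lam=self.lam, collapsing=self.collapsing)


ModelParams = Union[PUCParams, DDMParams]


def params_to_json(params: ModelParams, free: list[str] | None = None) -> str:
    """Serialize a parameter set (with optional free/fixed annotation)."""
    d = asdict(params)
    d["_type"] = type(params).__name__
    if free is not None:
        d["_free"] = list(free)
    return json.dumps(d, indent=2, sort_keys=True)


def params_from_json(text: str) -> ModelParams:
    d = json.loads(text)
    kind = d.pop("_type")
    d.pop("_free", None)
    if kind == "PUCParams":
        d["prior"] = PriorSpec(**d["prior"])
        return PUCParams(**d)
    if kind == "DDMParams":
        return DDMParams(**d)
    raise ValueError(f"unknown parameter type {kind!r}")
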