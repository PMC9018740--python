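"""Turnover scenarios and their parameterisations.

Three renewal scenarios for a homeostatic cell population:

* ``A``    — one constant turnover rate β (per year) for all cells.
* ``LIN``  — the rate changes linearly with age, parameterised by its
  values β₀ at age 0 and β₁₀ at age 10; the raw line is clamped to 0
  below 0 and to 0.5 /year above 0.5.
* ``2POP`` — a fraction ``f`` of cells renews at rate β while the
  remaining ``1 - f`` is quiescent and keeps its birth-time ¹⁴C.

Each scenario also carries the common Gaussian noise SD σ (‰) of the
measurement model.  Priors are uniform in log-rate for the rates
(log β ~ U(log 1e-6, log 0.5)), uniform on [0, 1] for ``f`` and uniform
on [0, 100] for σ.  The MCMC sampler works in exactly those uniform
coordinates (log-rates, f, σ), so the prior density is constant inside
the support and no Jacobian terms arise.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Union

import numpy as np

__all__ = [
    "RATE_MIN",
    "RATE_MAX",
    "SIGMA_MAX",
    "ScenarioAParams",
    "ScenarioLINParams",
    "Scenario2POPParams",
    "ScenarioParams",
    "get_scenario",
    "SCENARIO_NAMES",
    "turnover_rate",
]

RATE_MIN = 1e-6  # /year, lower prior bound for all turnover rates
RATE_MAX = 0.5  # /year, upper prior bound and LIN clamp ceiling
SIGMA_MAX = 100.0  # ‰, upper prior bound for the noise SD

_LOG_RATE_MIN = np.log(RATE_MIN)
_LOG_RATE_MAX = np.log(RATE_MAX)


def _check_rate(name: str, value: float) -> None:
    # physical sanity only; the prior box [RATE_MIN, RATE_MAX] is
    # enforced by log_prior / sampled_bounds, so e.g. beta = 0 (no
    # turnover) is a valid forward model outside the prior support
    if not (np.isfinite(value) and value >= 0.0):
        raise ValueError(f"{name} must be a finite non-negative rate (/year)")


def _check_sigma(value: float) -> None:
    if not (np.isfinite(value) and value >= 0.0):
        raise ValueError("sigma must be a finite non-negative SD (permil)")


@dataclass(frozen=True)
class ScenarioAParams:
    """Constant turnover: rate ``beta`` (/year), noise SD ``sigma`` (‰)."""

    beta: float
    sigma: float = 10.0

    scenario = "A"
    param_names = ("beta", "sigma")
    # sampler coordinates: (log beta, sigma)
    sampled_names = ("log_beta", "sigma")

    def __post_init__(self) -> None:
        _check_rate("beta", self.beta)
        _check_sigma(self.sigma)

    def rate(self, age) -> Union[float, np.ndarray]:
        age = _check_age(age)
        return np.broadcast_to(self.beta, np.shape(age)).copy() if np.ndim(age) else self.beta

    def to_sampled(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.array([np.log(self.beta), self.sigma])

    @classmethod
    def from_sampled(cls, theta) -> "ScenarioAParams":
        return cls(beta=float(np.exp(theta[0])), sigma=float(theta[1]))

    @classmethod
    def sampled_bounds(cls) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([_LOG_RATE_MIN, 0.0]),
            np.array([_LOG_RATE_MAX, SIGMA_MAX]),
        )


@dataclass(frozen=True)
class ScenarioLINParams:
    """Linearly changing turnover, anchored at ages 0 and 10 years.

    The instantaneous rate at age ``t`` is
    ``beta0 + (beta10 - beta0) * t / 10``, clamped to [0, 0.5] /year.
    """

    beta0: float
    beta10: float
    sigma: float = 10.0

    scenario = "LIN"
    param_names = ("beta0", "beta10", "sigma")
    sampled_names = ("log_beta0", "log_beta10", "sigma")

    def __post_init__(self) -> None:
        _check_rate("beta0", self.beta0)
        _check_rate("beta10", self.beta10)
        _check_sigma(self.sigma)

    def rate(self, age) -> Union[float, np.ndarray]:
        age = _check_age(age)
        raw = self.beta0 + (self.beta10 - self.beta0) * np.asarray(age) / 10.0
        out = np.clip(raw, 0.0, RATE_MAX)
        return float(out) if np.ndim(age) == 0 else out

    @property
    def annual_change(self) -> float:
        """Slope of the raw rate line, /year per year of age."""
        return (self.beta10 - self.beta0) / 10.0

    def to_sampled(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.array([np.log(self.beta0), np.log(self.beta10), self.sigma])

    @classmethod
    def from_sampled(cls, theta) -> "ScenarioLINParams":
        return cls(
            beta0=float(np.exp(theta[0])),
            beta10=float(np.exp(theta[1])),
            sigma=float(theta[2]),
        )

    @classmethod
    def sampled_bounds(cls) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([_LOG_RATE_MIN, _LOG_RATE_MIN, 0.0]),
            np.array([_LOG_RATE_MAX, _LOG_RATE_MAX, SIGMA_MAX]),
        )


@dataclass(frozen=True)
class Scenario2POPParams:
    """Quiescent + renewing mixture.

    ``f`` is the renewing fraction; ``beta`` the renewal rate of that
    fraction.  The whole-population turnover is the product ``f * beta``.
    """

    beta: float
    f: float
    sigma: float = 10.0

    scenario = "2POP"
    param_names = ("beta", "f", "sigma")
    sampled_names = ("log_beta", "f", "sigma")

    def __post_init__(self) -> None:
        _check_rate("beta", self.beta)
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must lie in [0, 1]")
        _check_sigma(self.sigma)

    def rate(self, age) -> Union[float, np.ndarray]:
        """Renewal rate of the renewing subpopulation (the quiescent
        fraction has rate 0 by construction)."""
        age = _check_age(age)
        return np.broadcast_to(self.beta, np.shape(age)).copy() if np.ndim(age) else self.beta

    @property
    def population_turnover(self) -> float:
        return self.f * self.beta

    def to_sampled(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.array([np.log(self.beta), self.f, self.sigma])

    @classmethod
    def from_sampled(cls, theta) -> "Scenario2POPParams":
        return cls(beta=float(np.exp(theta[0])), f=float(theta[1]), sigma=float(theta[2]))

    @classmethod
    def sampled_bounds(cls) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([_LOG_RATE_MIN, 0.0, 0.0]),
            np.array([_LOG_RATE_MAX, 1.0, SIGMA_MAX]),
        )


ScenarioParams = Union[ScenarioAParams, ScenarioLINParams, Scenario2POPParams]

_SCENARIOS = {
    "A": ScenarioAParams,
    "LIN": ScenarioLINParams,
    "2POP": Scenario2POPParams,
}
SCENARIO_NAMES = tuple(_SCENARIOS)


def get_scenario(name: str):
    """Return the parameter class for a scenario name (case-insensitive)."""
    try:
        return _SCENARIOS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def turnover_rate(params: ScenarioParams, age) -> Union[float, np.ndarray]:
    """Instantaneous turnover rate (/year) at a given age (years)."""
    return params.rate(age)


def _check_age(age):
    if np.any(np.asarray(age) < 0):
        raise ValueError("age must be non-negative")
    return age


def params_to_dict(params: ScenarioParams) -> dict:
    return {f.name: getattr(params, f.name) for f in fields(params)}
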