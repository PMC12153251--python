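"""Core monitoring statistics on the Brownian-motion B-value scale.

An interim test statistic in a two-arm trial behaves, under mild regularity
conditions, like a Brownian motion with drift observed at the *information
fraction* t = I / I_end (the ratio of current to final statistical
information).  The z-score Z(t) and the B-value B(t) = sqrt(t) * Z(t) are two
scales for the same process: B(t) is normal with mean theta*t and variance t,
has independent increments, and B(1) = Z(1) is the final test statistic.  The
*drift parameter* theta = E[Z(1)] links the design (power, alpha) to the
monitoring process.

This module provides the closed-form quantities built on that representation:
conditional power, the current-trend drift estimate, reverse conditional
power, predictive probability of success under a normal prior on the drift,
and the continuous-monitoring type II error bound for stochastic curtailment.

Sign convention throughout: positive z-scores favor treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

__all__ = [
    "InterimState",
    "DesignSpec",
    "PriorSpec",
    "InformationSpec",
    "information_fraction",
    "b_value",
    "drift_from_power",
    "power_from_drift",
    "conditional_power",
    "current_trend_drift",
    "reverse_conditional_power",
    "ppos",
    "continuous_curtailment_beta",
]

#: Default one-sided significance level.
DEFAULT_ALPHA = 0.025


def _check_prob(x: float, name: str, open_left: bool = True, open_right: bool = True) -> None:
    lo_ok = x > 0 if open_left else x >= 0
    hi_ok = x < 1 if open_right else x <= 1
    if not (lo_ok and hi_ok):
        raise ValueError(f"{name} must be a probability in the required range, got {x!r}")


@dataclass(frozen=True)
class InterimState:
    """One monitoring snapshot: information fraction plus z-score / B-value.

    May be constructed from ``(t, z)`` or ``(t, b)``; the missing member is
    derived via ``b = sqrt(t) * z``.
    """

    t: float
    z: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.t <= 1.0:
            raise ValueError(f"information fraction must be in (0, 1], got {self.t!r}")
        if self.z is None and self.b is None:
            raise ValueError("provide at least one of z (z-score) or b (B-value)")
        rt = math.sqrt(self.t)
        if self.z is None:
            object.__setattr__(self, "z", self.b / rt)
        elif self.b is None:
            object.__setattr__(self, "b", rt * self.z)
        elif abs(self.b - rt * self.z) > 1e-12:
            raise ValueError(
                f"inconsistent state: b={self.b!r} but sqrt(t)*z={rt * self.z!r}"
            )


@dataclass(frozen=True)
class DesignSpec:
    """Design-level quantities: one-sided alpha, power, critical value, drift.

    ``theta`` is the drift parameter, the expected final z-score under the
    design alternative; when not supplied it is derived from power and alpha
    as ``z_crit + Phi^{-1}(power)``.
    """

    alpha_one_sided: float = DEFAULT_ALPHA
    power: float = 0.9
    z_crit: float | None = None
    theta: float | None = None
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        _check_prob(self.alpha_one_sided, "alpha_one_sided")
        if self.alpha_one_sided >= 0.5:
            raise ValueError("one-sided alpha must be below 0.5")
        _check_prob(self.power, "power")
        object.__setattr__(self, "beta", 1.0 - self.power)
        if self.z_crit is None:
            object.__setattr__(self, "z_crit", float(norm.ppf(1.0 - self.alpha_one_sided)))
        if self.theta is None:
            object.__setattr__(
                self, "theta", float(self.z_crit + norm.ppf(self.power))
            )


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior on the drift parameter: mean ``theta0``, variance ``sigma0_sq``."""

    theta0: float
    sigma0_sq: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0_sq < 0:
            raise ValueError(f"prior variance must be >= 0, got {self.sigma0_sq!r}")


@dataclass(frozen=True)
class InformationSpec:
    """Current and final statistical information (or event / sample counts)."""

    current_info: float
    final_info: float

    def __post_init__(self) -> None:
        if not 0 < self.current_info <= self.final_info:
            raise ValueError(
                "need 0 < current_info <= final_info, got "
                f"({self.current_info!r}, {self.final_info!r})"
            )


def information_fraction(info: InformationSpec) -> float:
    """Information fraction t = I / I_end in (0, 1]."""
    return info.current_info / info.final_info


def b_value(t: float, z: float) -> float:
    """B-value B(t) = sqrt(t) * Z(t); at t = 1 this is the final z-score."""
    if not 0.0 < t <= 1.0:
        raise ValueError(f"information fraction must be in (0, 1], got {t!r}")
    return math.sqrt(t) * z


def drift_from_power(power: float, alpha_one_sided: float = DEFAULT_ALPHA,
                     z_crit: float | None = None) -> float:
    """Drift parameter giving the stated unconditional power.

    theta = z_crit + Phi^{-1}(power): e.g. 1.96 + 1.04 = 3.00 for 85% power
    at one-sided alpha 0.025.
    """
    _check_prob(power, "power")
    _check_prob(alpha_one_sided, "alpha_one_sided")
    if alpha_one_sided >= 0.5:
        raise ValueError("one-sided alpha must be below 0.5")
    if z_crit is None:
        z_crit = float(norm.ppf(1.0 - alpha_one_sided))
    return z_crit + float(norm.ppf(power))


def power_from_drift(theta: float, alpha_one_sided: float = DEFAULT_ALPHA,
                     z_crit: float | None = None) -> float:
    """Unconditional power Phi(theta - z_crit); inverse of :func:`drift_from_power`."""
    if z_crit is None:
        z_crit = float(norm.ppf(1.0 - alpha_one_sided))
    return float(norm.cdf(theta - z_crit))


def conditional_power(state: InterimState, theta: float, z_crit: float = 1.96) -> float:
    """Probability of final significance given the interim data and drift ``theta``.

    CP = Phi( (b + theta*(1-t) - z_crit) / sqrt(1-t) ).

    Undefined at t = 1 (compare z to z_crit directly at the final analysis).
    """
    t, b = state.t, state.b
    if t >= 1.0:
        raise ValueError("conditional power is undefined at t = 1; use the final test")
    return float(norm.cdf((b + theta * (1.0 - t) - z_crit) / math.sqrt(1.0 - t)))


def current_trend_drift(state: InterimState) -> float:
    """Drift estimate implied by the interim data alone: B(t)/t = z/sqrt(t)."""
    return state.b / state.t


def reverse_conditional_power(state: InterimState, z_crit: float = 1.96) -> float:
    """Probability of an interim result at least this disappointing, given a
    barely significant final result.

    RCP = P{B(t) <= z*sqrt(t) | B(1) = z_crit}
        = Phi( (z*sqrt(t) - z_crit*t) / sqrt(t*(1-t)) ).

    Does not depend on the drift parameter: conditioning on the final
    statistic removes the treatment effect.
    """
    t = state.t
    if not 0.0 < t < 1.0:
        raise ValueError(f"reverse conditional power needs t in (0, 1), got {t!r}")
    return float(norm.cdf((state.b - z_crit * t) / math.sqrt(t * (1.0 - t))))


def ppos(state: InterimState, prior: PriorSpec, z_crit: float = 1.96) -> float:
    """Predictive probability of success: conditional power averaged over the
    posterior of the drift under a normal prior N(theta0, sigma0_sq).

    PPoS(t) = Phi( [ (b - z_crit)(1 + t s0) + (1-t)(theta0 + b s0) ]
                   / sqrt( (1-t)(1 + s0)(1 + t s0) ) ),   s0 = sigma0_sq.

    With sigma0_sq = 0 this reduces exactly to conditional power at
    theta = theta0.
    """
    t, b = state.t, state.b
    if not 0.0 < t < 1.0:
        raise ValueError(f"PPoS needs t in (0, 1), got {t!r}")
    s0 = prior.sigma0_sq
    num = (b - z_crit) * (1.0 + t * s0) + (1.0 - t) * (prior.theta0 + b * s0)
    den = math.sqrt((1.0 - t) * (1.0 + s0) * (1.0 + t * s0))
    return float(norm.cdf(num / den))


def continuous_curtailment_beta(beta: float, gamma_threshold: float) -> float:
    """Type II error bound beta / (1 - Gamma) for continuous stochastic
    curtailment under the originally hypothesized effect (Lan-Simon-Halperin).
    """
    _check_prob(beta, "beta")
    if not 0.0 <= gamma_threshold < 1.0:
        raise ValueError(f"curtailment threshold must be in [0, 1), got {gamma_threshold!r}")
    return beta / (1.0 - gamma_threshold)
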