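"""Design-stage and mid-trial redesign helpers.

Everything the monitoring machinery needs is a drift parameter — the
expected final z-score.  This module converts endpoint-level summaries
(mean differences, event proportions, hazard ratios) to drifts, revises the
unconditional power when nuisance parameters are re-estimated mid-trial, and
implements two simple futility procedures from the cancer-trials literature:
the Wieand single-look rule and the Freidlin-Korn-Gray "inefficacy"
monitoring strategies that start at the information time t0 where a wrong-way
trend first makes the nominal confidence interval exclude the design effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.stats import norm

from .brownian_core import DesignSpec, InterimState

__all__ = [
    "EndpointSpec",
    "InefficacySpec",
    "InefficacyDecision",
    "drift_from_endpoint",
    "revised_power",
    "freidlin_t0",
    "inefficacy_check",
    "wieand_check",
]


@dataclass(frozen=True)
class EndpointSpec:
    """Endpoint-level design summary, convertible to a drift parameter.

    kind = "continuous":  ``effect`` is the mean difference delta, ``sd`` the
    common standard deviation, ``n_per_arm`` the final per-arm size.

    kind = "binary":  ``p_control`` / ``p_intervention`` are the design event
    proportions, ``n_per_arm`` the final per-arm size; benefit means fewer
    events on intervention.

    kind = "survival":  ``hazard_ratio`` and the target event count
    ``events``; ``allocation`` selects the approximation
    |theta| = |ln HR| sqrt(D/4) (1:1) or sqrt(2D/9) (2:1).
    """

    kind: Literal["continuous", "binary", "survival"]
    effect: float | None = None
    sd: float | None = None
    n_per_arm: int | None = None
    p_control: float | None = None
    p_intervention: float | None = None
    hazard_ratio: float | None = None
    events: int | None = None
    allocation: Literal["1:1", "2:1"] = "1:1"


def drift_from_endpoint(spec: EndpointSpec) -> float:
    """Expected final z-score implied by an endpoint-level design summary.

    Oriented so benefit is positive: a positive mean difference, a lower
    event proportion on intervention, or a hazard ratio below 1 all give
    theta > 0.
    """
    if spec.kind == "continuous":
        if spec.sd is None or spec.n_per_arm is None or spec.effect is None:
            raise ValueError("continuous endpoint needs effect, sd and n_per_arm")
        if spec.sd <= 0 or spec.n_per_arm <= 0:
            raise ValueError("sd and n_per_arm must be positive")
        se_end = spec.sd * math.sqrt(2.0 / spec.n_per_arm)
        return spec.effect / se_end
    if spec.kind == "binary":
        pc, pi_ = spec.p_control, spec.p_intervention
        if pc is None or pi_ is None or spec.n_per_arm is None:
            raise ValueError("binary endpoint needs p_control, p_intervention, n_per_arm")
        var = pc * (1 - pc) / spec.n_per_arm + pi_ * (1 - pi_) / spec.n_per_arm
        if var <= 0:
            raise ValueError("degenerate event proportions give zero variance")
        return (pc - pi_) / math.sqrt(var)
    if spec.kind == "survival":
        if spec.hazard_ratio is None or spec.events is None:
            raise ValueError("survival endpoint needs hazard_ratio and events")
        if spec.hazard_ratio <= 0 or spec.events <= 0:
            raise ValueError("hazard ratio and event target must be positive")
        c = math.sqrt(spec.events / 4.0) if spec.allocation == "1:1" \
            else math.sqrt(2.0 * spec.events / 9.0)
        return -math.log(spec.hazard_ratio) * c
    raise ValueError(f"unknown endpoint kind {spec.kind!r}")


def revised_power(theta_revised: float, z_crit: float = 1.96) -> float:
    """Unconditional power Phi(theta - z_crit) at a revised drift.

    Recomputing the design power with interim-updated nuisance parameters
    (event rates, variances) answers the second futility question: would a
    null result still be meaningful, or is the trial simply underpowered to
    answer its question?
    """
    return float(norm.cdf(theta_revised - z_crit))


def freidlin_t0(alpha_one_sided: float = 0.025, beta: float = 0.10) -> float:
    """Information time at which inefficacy monitoring starts:
    t0 = (1.96 / (z_{alpha/2} + z_beta))^2.

    At t0, a z-score of exactly 0 makes the nominal two-sided 95% confidence
    interval for the treatment effect just exclude the effect the trial was
    powered for.  The numerator uses the exact 97.5% normal quantile (1.96 is
    its conventional rounding) so this tangency is exact.
    """
    if not 0.0 < alpha_one_sided < 0.5:
        raise ValueError("one-sided alpha must be in (0, 0.5)")
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    denom = float(norm.ppf(1.0 - alpha_one_sided) + norm.ppf(1.0 - beta))
    return (float(norm.ppf(0.975)) / denom) ** 2


@dataclass(frozen=True)
class InefficacySpec:
    """Freidlin-Korn-Gray inefficacy monitoring configuration.

    Strategy 1: from t0 on, stop whenever Z(t) < 0.
    Strategy 2: at t0 stop iff Z(t0) < 0; afterwards stop when the nominal
    95% confidence interval for the drift, z/sqrt(t) +/- 1.96/sqrt(t),
    lies entirely below the design drift.
    Strategy 3: as 2, but the interval must clear the design drift by a
    margin growing linearly from 0 at t0 to one extra interval half-width at
    t = 1, making late stopping progressively more difficult.
    """

    strategy: Literal[1, 2, 3] = 1
    alpha_two_sided_nominal: float = 0.05

    def __post_init__(self) -> None:
        if self.strategy not in (1, 2, 3):
            raise ValueError(f"strategy must be 1, 2 or 3, got {self.strategy!r}")


@dataclass(frozen=True)
class InefficacyDecision:
    stop: bool
    strategy: int
    t0: float
    margin: float
    reason: str


def inefficacy_check(
    spec: InefficacySpec, state: InterimState, design: DesignSpec
) -> InefficacyDecision:
    """Apply a Freidlin-Korn-Gray inefficacy strategy at one interim look."""
    t, z = state.t, state.z
    t0 = freidlin_t0(design.alpha_one_sided, design.beta)
    zq = float(norm.ppf(1.0 - spec.alpha_two_sided_nominal / 2.0))
    if t < t0:
        return InefficacyDecision(False, spec.strategy, t0, 0.0,
                                  f"monitoring has not started (t={t:.3f} < t0={t0:.3f})")
    if spec.strategy == 1:
        stop = z < 0.0
        why = "z-score below 0" if stop else "z-score not below 0"
        return InefficacyDecision(stop, 1, t0, 0.0, why)
    # strategies 2 and 3: drift-scale CI upper limit vs the design drift
    half = zq / math.sqrt(t)
    upper = z / math.sqrt(t) + half
    margin = 0.0
    if spec.strategy == 3 and t > t0:
        margin = half * (t - t0) / (1.0 - t0)
    stop = upper < design.theta - margin
    why = (
        f"CI upper limit {upper:.3f} {'<' if stop else '>='} design drift "
        f"{design.theta:.3f}" + (f" minus margin {margin:.3f}" if margin else "")
    )
    return InefficacyDecision(stop, spec.strategy, t0, margin, why)


def wieand_check(z_halfway: float) -> bool:
    """Wieand single-look rule: at half the target events, results going in
    the wrong direction (z < 0, i.e. more events on treatment) flag futility.
    Returns True when stopping should be discussed."""
    return z_halfway < 0.0
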