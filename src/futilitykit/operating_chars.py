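"""Operating characteristics of futility stopping rules.

A futility rule ("stop if conditional power under the current trend is at or
below 0.20", "stop if reverse conditional power is at or below 0.025", ...)
is, at each interim look, equivalent to a threshold on the interim z-score.
This module inverts the closed-form monitoring statistics to those per-look
z-thresholds and evaluates the resulting type II error exactly with the
recursive integration engine: under the design drift, a type II error occurs
by stopping for futility at an interim look or by reaching the final analysis
and failing the significance test.

No interim efficacy boundary is assumed by default (pure futility monitoring);
a design with efficacy boundaries can be evaluated by passing finite upper
bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .brownian_core import DesignSpec
from .gs_engine import BoundarySet, LookSchedule, crossing_probabilities

__all__ = [
    "FutilityRule",
    "OCResult",
    "rule_to_z_thresholds",
    "type2_error",
    "table_sweep",
]

RULE_KINDS = ("cp_original", "cp_current_trend", "rcp", "z_threshold")


@dataclass(frozen=True)
class FutilityRule:
    """A stop-for-futility guideline applied at interim looks only.

    ``threshold`` is the curtailment level Gamma for the conditional-power
    kinds, the cutoff for ``rcp``, or a raw z-value for ``z_threshold``.
    Stopping uses <= : the rule triggers when the statistic drops to the
    threshold or below.
    """

    kind: str
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}; pick one of {RULE_KINDS}")
        if self.kind != "z_threshold" and not 0.0 < self.threshold < 1.0:
            raise ValueError(
                f"probability threshold must be in (0, 1), got {self.threshold!r}"
            )


@dataclass(frozen=True)
class OCResult:
    """Type II error decomposition for a futility rule."""

    type2_error: float
    per_look_stop_prob: tuple[float, ...]
    p_fail_final: float


def rule_to_z_thresholds(
    rule: FutilityRule, schedule: LookSchedule, design: DesignSpec
) -> tuple[float, ...]:
    """Largest interim z-score at which the rule triggers, per interim look.

    Closed-form inversions of the monitoring statistics:

    * ``cp_current_trend`` at level Gamma:  CP under theta-hat = z/sqrt(t)
      collapses to Phi((b/t - z_crit)/sqrt(1-t)), so the threshold is
      z = sqrt(t) * (z_crit + Phi^{-1}(Gamma) * sqrt(1-t)).
    * ``cp_original``:  solve CP(t, z, theta) = Gamma for z.
    * ``rcp``:  z = z_crit*sqrt(t) + Phi^{-1}(threshold) * sqrt(1-t).
    * ``z_threshold``:  passed through unchanged.
    """
    zc = design.z_crit
    out = []
    for t in schedule.times:
        if t >= 1.0:
            raise ValueError("futility rules apply at interim looks only (t < 1)")
        rt, r1t = math.sqrt(t), math.sqrt(1.0 - t)
        if rule.kind == "z_threshold":
            out.append(float(rule.threshold))
            continue
        q = float(norm.ppf(rule.threshold))
        if rule.kind == "cp_current_trend":
            out.append(rt * (zc + q * r1t))
        elif rule.kind == "cp_original":
            # b + theta(1-t) - z_crit = q * sqrt(1-t)
            b = zc - design.theta * (1.0 - t) + q * r1t
            out.append(b / rt)
        else:  # rcp
            out.append(zc * rt + q * r1t)
    return tuple(out)


def type2_error(
    rule: FutilityRule,
    schedule: LookSchedule,
    design: DesignSpec,
    upper: Sequence[float] | None = None,
) -> OCResult:
    """Exact type II error of a futility rule over a look schedule.

    The schedule must end at t = 1, where benefit is declared iff
    Z(1) >= z_crit; the rule is converted to z-thresholds at the interim
    looks and the stop-or-fail probability is computed under the design
    drift by recursive numerical integration.  ``upper`` adds interim
    efficacy boundaries (default: none).
    """
    times = schedule.times
    if times[-1] != 1.0:
        raise ValueError("the schedule must include the final analysis at t = 1")
    interim = LookSchedule(times[:-1]) if len(times) > 1 else None
    thresholds = (
        rule_to_z_thresholds(rule, interim, design) if interim is not None else ()
    )
    lower = tuple(thresholds) + (design.z_crit,)
    if upper is None:
        upper = (np.inf,) * len(times)
    res = crossing_probabilities(BoundarySet(schedule, lower, upper), design.theta)
    return OCResult(
        type2_error=res.total_lower,
        per_look_stop_prob=res.fcp_lower[:-1],
        p_fail_final=res.fcp_lower[-1],
    )


def table_sweep(
    kind: str,
    threshold: float,
    powers: Sequence[float],
    k_values: Sequence[int],
    alpha_one_sided: float = 0.025,
) -> pd.DataFrame:
    """Type II error of a rule over a grid of design powers and numbers of
    equally spaced looks (K total analyses; futility at the K-1 interims).

    Returns a DataFrame indexed by unconditional power with one column per K.
    The K = 1 column is the design beta exactly: with no interim look the
    only type II error is failing the final test.
    """
    rule = FutilityRule(kind, threshold)
    rows = {}
    for p in powers:
        design = DesignSpec(alpha_one_sided=alpha_one_sided, power=p)
        rows[p] = {
            k: type2_error(rule, LookSchedule.equally_spaced(k), design).type2_error
            for k in k_values
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "power"
    df.columns.name = "looks"
    return df
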