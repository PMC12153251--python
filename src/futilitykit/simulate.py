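"""Monte-Carlo oracle and fixture generation.

Simulates the monitored trial directly from the B-value representation:
B-value paths are sums of independent normal increments with mean
theta * dt and variance dt between looks, converted to z-scores by
Z(t) = B(t) / sqrt(t).  Applying a futility rule or boundary set path by
path gives empirical operating characteristics with standard errors — the
independent cross-check for every probability the numerical-integration
engine computes.  A binomial generator provides synthetic interim states for
the predicted-interval machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .brownian_core import DesignSpec
from .gs_engine import BoundarySet, LookSchedule
from .operating_chars import FutilityRule, rule_to_z_thresholds
from .predicted_intervals import BinaryTrialState

__all__ = [
    "PathBatch",
    "EmpiricalOC",
    "simulate_paths",
    "apply_rule_to_paths",
    "simulate_binary_trial",
]


@dataclass(frozen=True)
class PathBatch:
    """Replicates-by-looks matrix of simulated interim z-scores."""

    schedule: LookSchedule
    z_matrix: np.ndarray
    theta: float
    seed: int

    @property
    def n_rep(self) -> int:
        return self.z_matrix.shape[0]


def simulate_paths(
    schedule: LookSchedule, theta: float, n_rep: int, seed: int
) -> PathBatch:
    """Simulate z-score paths of a drifted Brownian motion at the look times.

    Built from independent B-value increments: B(t_{j}) - B(t_{j-1}) is
    N(theta * dt, dt).  Column j of the result then has mean theta*sqrt(t_j)
    and unit variance, with cov(Z(t_i), Z(t_j)) = sqrt(t_i / t_j).
    """
    if n_rep < 1:
        raise ValueError("need at least one replicate")
    times = np.asarray(schedule.times)
    dts = np.diff(np.concatenate(([0.0], times)))
    rng = np.random.default_rng(seed)
    incs = rng.normal(loc=theta * dts, scale=np.sqrt(dts), size=(n_rep, len(times)))
    b = np.cumsum(incs, axis=1)
    z = b / np.sqrt(times)
    return PathBatch(schedule, z, float(theta), int(seed))


@dataclass(frozen=True)
class EmpiricalOC:
    """Empirical operating characteristics with Monte-Carlo standard errors."""

    type2_error: float
    type2_se: float
    per_look_stop_prob: tuple[float, ...]
    p_fail_final: float
    n_rep: int

    def se(self, p: float) -> float:
        return math.sqrt(max(p * (1.0 - p), 0.0) / self.n_rep)


def _first_crossing_counts(
    z: np.ndarray, lower: np.ndarray, upper: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-look first-crossing counts below `lower` / above `upper` and the
    number of paths that never cross."""
    n_rep, k = z.shape
    alive = np.ones(n_rep, dtype=bool)
    low_counts = np.zeros(k, dtype=np.int64)
    up_counts = np.zeros(k, dtype=np.int64)
    for j in range(k):
        cross_low = alive & (z[:, j] <= lower[j])
        cross_up = alive & (z[:, j] >= upper[j]) & ~cross_low
        low_counts[j] = int(cross_low.sum())
        up_counts[j] = int(cross_up.sum())
        alive &= ~(cross_low | cross_up)
    return low_counts, up_counts, int(alive.sum())


def apply_rule_to_paths(
    batch: PathBatch,
    rule: FutilityRule | BoundarySet,
    z_crit: float = 1.96,
    design: DesignSpec | None = None,
) -> EmpiricalOC:
    """Empirical type II error of a futility rule or boundary set on a batch.

    For a :class:`FutilityRule` the batch schedule must end at t = 1: the
    rule is applied at the interim looks (stop when z is at or below the
    threshold) and the final look fails when Z(1) < z_crit.  For a
    :class:`BoundarySet` the boundaries are applied as given (a path stops
    below at z <= lower, above at z >= upper) and the type II error is the
    total lower-crossing fraction.
    """
    times = batch.schedule.times
    if isinstance(rule, BoundarySet):
        if rule.schedule.times != times:
            raise ValueError("boundary schedule does not match the batch schedule")
        lower = np.asarray(rule.lower)
        upper = np.asarray(rule.upper)
    else:
        if times[-1] != 1.0:
            raise ValueError("a futility rule needs the final analysis at t = 1")
        if design is None:
            design = DesignSpec(theta=batch.theta)
        interim = LookSchedule(times[:-1]) if len(times) > 1 else None
        thr = rule_to_z_thresholds(rule, interim, design) if interim else ()
        # final look: fail (type II) below z_crit, succeed at or above it
        lower = np.asarray(tuple(thr) + (z_crit,))
        upper = np.concatenate((np.full(len(times) - 1, np.inf), [z_crit]))
    low, up, _ = _first_crossing_counts(batch.z_matrix, lower, upper)
    n = batch.n_rep
    p2 = float(low.sum()) / n
    return EmpiricalOC(
        type2_error=p2,
        type2_se=math.sqrt(max(p2 * (1.0 - p2), 0.0) / n),
        per_look_stop_prob=tuple(low[:-1] / n),
        p_fail_final=float(low[-1]) / n,
        n_rep=n,
    )


def simulate_binary_trial(
    pi_c: float,
    pi_i: float,
    N_c: int,
    N_i: int,
    interim_fraction: float,
    seed: int,
    pi_c_future: float | None = None,
    pi_i_future: float | None = None,
) -> BinaryTrialState:
    """Synthetic interim state of a two-arm binary trial.

    Interim event counts are Binomial draws at the interim sample sizes
    (``interim_fraction`` of the per-arm targets); the future-data
    assumptions default to the same true probabilities.
    """
    if not 0.0 < interim_fraction <= 1.0:
        raise ValueError(f"interim fraction must be in (0, 1], got {interim_fraction!r}")
    if min(N_c, N_i) < 1:
        raise ValueError("per-arm targets must be at least 1")
    for p in (pi_c, pi_i):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"event probability out of [0, 1]: {p!r}")
    rng = np.random.default_rng(seed)
    n_c = int(round(interim_fraction * N_c))
    n_i = int(round(interim_fraction * N_i))
    x_c = int(rng.binomial(n_c, pi_c))
    x_i = int(rng.binomial(n_i, pi_i))
    return BinaryTrialState(
        N_c=N_c, N_i=N_i, n_c=n_c, n_i=n_i, x_c=x_c, x_i=x_i,
        pi_c=pi_c if pi_c_future is None else pi_c_future,
        pi_i=pi_i if pi_i_future is None else pi_i_future,
    )
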