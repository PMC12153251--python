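"""Group-sequential numerics: spending functions, first-crossing probabilities,
and boundary derivation.

The interim z-scores Z(t_1), ..., Z(t_k) of a monitored trial are jointly
normal; on the B-value scale (B = sqrt(t) * Z) the increments between looks
are independent normals with mean theta * dt and variance dt.  All crossing
probabilities here are computed by the classical recursive numerical
integration over that Markov chain: the sub-density of not-yet-stopped paths
is propagated look to look with Gauss-Legendre quadrature.

Three layers:

* spending functions (O'Brien-Fleming-like, Hwang-Shih-DeCani gamma family,
  custom tabulated) prescribing cumulative type I or type II error by
  information time;
* ``crossing_probabilities`` — per-look first-crossing probabilities below a
  lower and above an upper z-boundary under a given drift;
* boundary construction: ``alpha_boundaries`` (efficacy boundaries from alpha
  spending, futility ignored — the non-binding convention) and
  ``beta_boundaries_and_drift`` (futility boundaries from beta spending,
  efficacy boundaries respected, with the drift calibrated so the total
  type II error equals the spending total).

All numerics are deterministic; no seeds are involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "InfeasibleSpendingError",
    "LookSchedule",
    "SpendingSpec",
    "BoundarySet",
    "CrossingResult",
    "spend",
    "crossing_probabilities",
    "alpha_boundaries",
    "beta_boundaries_and_drift",
]

#: Gauss-Legendre nodes per look interval.  301 nodes with the +/- 8 sd
#: truncation gives ~1e-8 accuracy on crossing probabilities, far inside the
#: 4-decimal reporting precision of boundary tables.
N_NODES = 301

#: Truncation half-width of integration ranges, in standard deviations.
TRUNC_SD = 8.0


class InfeasibleSpendingError(ValueError):
    """A spending increment exceeds the probability mass still in play."""


@dataclass(frozen=True)
class LookSchedule:
    """Ordered information fractions t_1 < ... < t_k with t_k <= 1."""

    times: tuple[float, ...]

    def __init__(self, times: Sequence[float]):
        times = tuple(float(t) for t in times)
        if len(times) == 0:
            raise ValueError("schedule needs at least one look")
        if any(not 0.0 < t <= 1.0 for t in times):
            raise ValueError(f"look times must lie in (0, 1], got {times!r}")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"look times must be strictly increasing, got {times!r}")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def equally_spaced(cls, k: int) -> "LookSchedule":
        """K analyses at t = j/K, j = 1..K (final look included)."""
        if k < 1:
            raise ValueError("need at least one look")
        return cls(tuple((j + 1) / k for j in range(k)))


@dataclass(frozen=True)
class SpendingSpec:
    """Error-spending function: family, parameters, and total error to spend.

    Families
    --------
    ``obf_like``
        2 * (1 - Phi(z_{total/2} / sqrt(t))) — the Lan-DeMets approximation
        to O'Brien-Fleming boundaries.
    ``hsd_gamma``
        total * (1 - exp(-gamma * t)) / (1 - exp(-gamma)); gamma < 0 spends
        conservatively (late), gamma > 0 aggressively (early).  gamma = 0 is
        the removable singularity and is defined by its limit, linear
        spending total * t.
    ``custom``
        linear interpolation of a tabulated (t, cumulative-spend) curve; the
        table must start at (0, 0) and end at (1, total).
    """

    family: str
    total: float
    gamma: float | None = None
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("obf_like", "hsd_gamma", "custom"):
            raise ValueError(f"unknown spending family {self.family!r}")
        if not 0.0 < self.total < 1.0:
            raise ValueError(f"total error to spend must be in (0, 1), got {self.total!r}")
        if self.family == "hsd_gamma" and self.gamma is None:
            raise ValueError("hsd_gamma requires a gamma parameter")
        if self.family == "custom":
            if not self.table:
                raise ValueError("custom family requires a table of (t, spend) points")
            tab = tuple((float(a), float(b)) for a, b in self.table)
            if tab[0] != (0.0, 0.0) or abs(tab[-1][0] - 1.0) > 1e-12:
                raise ValueError("custom table must run from (0, 0) to (1, total)")
            object.__setattr__(self, "table", tab)


def spend(spec: SpendingSpec, t: float) -> float:
    """Cumulative error spent by information time t; spend(0)=0, spend(1)=total."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"information time must be in [0, 1], got {t!r}")
    if t == 0.0:
        return 0.0
    if spec.family == "obf_like":
        z_half = norm.ppf(1.0 - spec.total / 2.0)
        return float(2.0 * (1.0 - norm.cdf(z_half / math.sqrt(t))))
    if spec.family == "hsd_gamma":
        g = spec.gamma
        if g == 0.0:  # analytic limit of the gamma family
            return spec.total * t
        return spec.total * (1.0 - math.exp(-g * t)) / (1.0 - math.exp(-g))
    ts, ss = zip(*spec.table)
    return float(np.interp(t, ts, ss))


@dataclass(frozen=True)
class BoundarySet:
    """Per-look lower (futility) and upper (efficacy) z-score boundaries.

    ``-inf`` / ``+inf`` entries mean no boundary on that side at that look.
    """

    schedule: LookSchedule
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.schedule)
        lower = tuple(float(x) for x in self.lower)
        upper = tuple(float(x) for x in self.upper)
        if len(lower) != k or len(upper) != k:
            raise ValueError("boundary lengths must match the schedule")
        if any(l > u for l, u in zip(lower, upper)):
            raise ValueError("lower boundary exceeds upper boundary at some look")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)


@dataclass(frozen=True)
class CrossingResult:
    """Per-look first-crossing probabilities and the never-crossing remainder."""

    fcp_lower: tuple[float, ...]
    fcp_upper: tuple[float, ...]
    p_continue: float

    @property
    def total_lower(self) -> float:
        return float(sum(self.fcp_lower))

    @property
    def total_upper(self) -> float:
        return float(sum(self.fcp_upper))


def _gauss_legendre(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


class _Recursion:
    """Propagates the sub-density of not-yet-stopped B-value paths.

    State after look j: quadrature nodes ``x`` in the continuation interval
    [L_j, U_j] (B-value scale, truncated at +/- TRUNC_SD increments), weights
    ``w``, and sub-density values ``g`` such that sums of w*g*f(x) integrate
    f against the joint density of {B(t_j), no boundary crossed so far}.
    """

    def __init__(self, theta: float, n_nodes: int = N_NODES):
        self.theta = theta
        self.n_nodes = n_nodes
        self.x: np.ndarray | None = None
        self.w: np.ndarray | None = None
        self.g: np.ndarray | None = None
        self.t_prev: float = 0.0
        self.dead = False  # continuation region exhausted

    # -- predictive pieces for the next look (before restricting to [L, U]) --

    def _inc(self, t: float) -> tuple[float, float]:
        dt = t - self.t_prev
        return self.theta * dt, math.sqrt(dt)

    def p_below(self, t: float, L: float) -> float:
        """P(B(t) < L, not stopped before)."""
        if not np.isfinite(L):
            return 0.0 if L < 0 else self.mass()
        m, s = self._inc(t)
        if self.x is None:  # first look: B(t) ~ N(theta*t, t)
            return float(norm.cdf((L - m) / s))
        return float(np.sum(self.w * self.g * norm.cdf((L - self.x - m) / s)))

    def p_above(self, t: float, U: float) -> float:
        """P(B(t) > U, not stopped before)."""
        if not np.isfinite(U):
            return 0.0 if U > 0 else self.mass()
        m, s = self._inc(t)
        if self.x is None:
            return float(norm.sf((U - m) / s))
        return float(np.sum(self.w * self.g * norm.sf((U - self.x - m) / s)))

    def mass(self) -> float:
        """Probability of not having stopped yet."""
        if self.x is None:
            return 1.0
        return float(np.sum(self.w * self.g))

    def restrict(self, t: float, L: float, U: float) -> None:
        """Advance to look time t and keep only paths with B(t) in [L, U]."""
        m, s = self._inc(t)
        if self.x is None:
            lo_reach, hi_reach = m - TRUNC_SD * s, m + TRUNC_SD * s
        else:
            lo_reach = float(self.x.min()) + m - TRUNC_SD * s
            hi_reach = float(self.x.max()) + m + TRUNC_SD * s
        a = max(L, lo_reach) if np.isfinite(L) else lo_reach
        b = min(U, hi_reach) if np.isfinite(U) else hi_reach
        if a >= b:
            self.dead = True
            self.x = np.empty(0)
            self.w = np.empty(0)
            self.g = np.empty(0)
            self.t_prev = t
            return
        y, wy = _gauss_legendre(a, b, self.n_nodes)
        if self.x is None:
            gy = norm.pdf(y, loc=m, scale=s)
        else:
            # kernel: density of the independent increment B(t) - B(t_prev)
            gy = norm.pdf(y[:, None], loc=self.x[None, :] + m, scale=s) @ (self.w * self.g)
        self.x, self.w, self.g = y, wy, gy
        self.t_prev = t


def crossing_probabilities(
    bounds: BoundarySet, theta: float, n_nodes: int = N_NODES
) -> CrossingResult:
    """First-crossing probabilities of a discretely monitored drifted Brownian
    motion through the given z-score boundaries.

    At look j the path stops below if Z(t_j) < lower_j (first time), stops
    above if Z(t_j) > upper_j, and otherwise continues.  Probabilities are
    exact joint-normal quantities computed by recursive quadrature; the
    entries plus ``p_continue`` sum to one.
    """
    if not np.isfinite(theta):
        raise ValueError(f"drift must be finite, got {theta!r}")
    times = bounds.schedule.times
    rec = _Recursion(theta, n_nodes)
    fcl, fcu = [], []
    for t, lz, uz in zip(times, bounds.lower, bounds.upper):
        rt = math.sqrt(t)
        L = lz * rt if np.isfinite(lz) else -np.inf
        U = uz * rt if np.isfinite(uz) else np.inf
        if rec.dead:
            fcl.append(0.0)
            fcu.append(0.0)
            continue
        fcl.append(max(rec.p_below(t, L), 0.0))
        fcu.append(max(rec.p_above(t, U), 0.0))
        rec.restrict(t, L, U)
    p_cont = 0.0 if rec.dead else max(rec.mass(), 0.0)
    return CrossingResult(tuple(fcl), tuple(fcu), p_cont)


def alpha_boundaries(
    schedule: LookSchedule, alpha_spec: SpendingSpec, n_nodes: int = N_NODES
) -> tuple[float, ...]:
    """Efficacy (upper) z-boundaries from an alpha-spending function.

    Solved under the null drift with no lower boundary (non-binding futility
    convention): at each look the first-upper-crossing probability equals the
    spending increment.  A zero increment yields an infinite boundary at that
    look.
    """
    if not 0.0 < alpha_spec.total < 0.5:
        raise ValueError("total one-sided alpha must be in (0, 0.5)")
    times = schedule.times
    cum = [spend(alpha_spec, t) for t in times]
    incs = np.diff([0.0] + cum)
    rec = _Recursion(0.0, n_nodes)
    uppers: list[float] = []
    for t, inc in zip(times, incs):
        rt = math.sqrt(t)
        if inc <= 0.0:
            uppers.append(np.inf)
            rec.restrict(t, -np.inf, np.inf)
            continue
        remaining = rec.mass()
        if inc >= remaining:
            raise ValueError(
                f"alpha-spending increment {inc:.3g} at t={t} exceeds the "
                f"remaining continuation probability {remaining:.3g}"
            )
        if rec.x is None:
            U = float(norm.isf(inc)) * rt  # closed form at the first look
        else:
            lo = float(rec.x.min()) - TRUNC_SD * math.sqrt(t - rec.t_prev)
            hi = float(rec.x.max()) + TRUNC_SD * math.sqrt(t - rec.t_prev)
            U = brentq(lambda u: rec.p_above(t, u) - inc, lo, hi, xtol=1e-12)
        uppers.append(U / rt)
        rec.restrict(t, -np.inf, U)
    return tuple(uppers)


@dataclass(frozen=True)
class BetaSolveResult:
    """Outcome of the coupled futility-boundary / drift calibration."""

    bounds: BoundarySet
    theta: float
    total_type2: float
    clamped_looks: tuple[int, ...] = ()


def _solve_lowers(
    schedule: LookSchedule,
    incs: np.ndarray,
    upper: Sequence[float],
    theta: float,
    n_nodes: int,
) -> tuple[list[float], float, list[int]]:
    """Lower boundaries matching beta-spending increments at looks 1..k-1 for
    a fixed drift; returns (lower z-boundaries incl. final, total type II,
    looks clamped to the upper boundary)."""
    times = schedule.times
    k = len(times)
    rec = _Recursion(theta, n_nodes)
    lowers: list[float] = []
    clamped: list[int] = []
    total = 0.0
    for j in range(k - 1):
        t = times[j]
        rt = math.sqrt(t)
        uz = upper[j]
        U = uz * rt if np.isfinite(uz) else np.inf
        inc = float(incs[j])
        if inc <= 0.0:
            L = -np.inf
        else:
            # feasibility: the increment cannot exceed the mass that can
            # still reach below the upper boundary at this look
            avail = rec.mass() - rec.p_above(t, U)
            if inc >= avail:
                raise InfeasibleSpendingError(
                    f"beta-spending increment {inc:.3g} at look {j + 1} exceeds the "
                    f"available probability mass {avail:.3g}; spending is infeasible"
                )
            if rec.x is None:
                L = theta * t + rt * float(norm.ppf(inc))
            else:
                s = math.sqrt(t - rec.t_prev)
                lo = float(rec.x.min()) + theta * (t - rec.t_prev) - TRUNC_SD * s
                hi = float(rec.x.max()) + theta * (t - rec.t_prev) + TRUNC_SD * s
                L = brentq(lambda v: rec.p_below(t, v) - inc, lo, hi, xtol=1e-12)
            if L > U:
                L = U
                clamped.append(j + 1)
            total += rec.p_below(t, L)
        lowers.append(L / rt if np.isfinite(L) else -np.inf)
        # upper crossings are efficacy stops, not type II error
        rec.restrict(t, L, U)
    # final look: l_k = u_k; failing there without a prior efficacy stop is
    # the remaining type II error
    t_k = times[-1]
    uk = upper[-1]
    total += rec.p_below(t_k, uk * math.sqrt(t_k))
    lowers.append(uk)
    return lowers, total, clamped


def beta_boundaries_and_drift(
    schedule: LookSchedule,
    beta_spec: SpendingSpec,
    upper: Sequence[float],
    n_nodes: int = N_NODES,
    theta_bracket: tuple[float, float] = (0.0, 10.0),
    theta_tol: float = 1e-8,
) -> BetaSolveResult:
    """Futility boundaries from beta spending, with the drift calibrated so
    the total type II error equals the spending total.

    For a candidate drift, lower boundaries l_1..l_{k-1} are solved
    sequentially so the first-lower-crossing probability at look j (efficacy
    boundaries respected) equals the beta-spending increment; l_k is set to
    u_k so the final analysis has an unambiguous verdict.  The total type II
    error — all lower crossings plus failing the final test without a prior
    efficacy stop — is monotone decreasing in the drift, and the drift is
    found by root bracketing.

    The returned drift exceeds the no-monitoring drift for the same beta:
    interim futility looks spend power, so a larger effect (sample size) is
    needed to keep the type II error at its nominal total.
    """
    times = schedule.times
    k = len(times)
    if len(upper) != k:
        raise ValueError("need one upper boundary per look")
    if not np.isfinite(upper[-1]):
        raise ValueError("the final upper boundary must be finite (l_k = u_k)")
    cum = [spend(beta_spec, t) for t in times]
    incs = np.diff([0.0] + cum)

    def total_type2(theta: float) -> float:
        # a drift so large that efficacy crossings exhaust the mass before the
        # spending can be placed has, for bracketing purposes, no type II error
        try:
            return _solve_lowers(schedule, incs, upper, theta, n_nodes)[1]
        except InfeasibleSpendingError:
            return 0.0

    lo, hi = theta_bracket
    f_lo = total_type2(lo) - beta_spec.total
    f_hi = total_type2(hi) - beta_spec.total
    if f_lo * f_hi > 0:
        raise ValueError(
            "drift bracket does not straddle the target type II error; "
            f"total at {lo} is {f_lo + beta_spec.total:.4g}, at {hi} is "
            f"{f_hi + beta_spec.total:.4g}"
        )
    theta = brentq(lambda th: total_type2(th) - beta_spec.total, lo, hi, xtol=theta_tol)
    lowers, total, clamped = _solve_lowers(schedule, incs, upper, theta, n_nodes)
    bounds = BoundarySet(schedule, tuple(lowers), tuple(float(u) for u in upper))
    return BetaSolveResult(bounds, float(theta), float(total), tuple(clamped))
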