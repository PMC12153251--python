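"""Predicted intervals and predicted-interval plots (PIPs).

A predicted interval answers the estimation-side question at an interim
analysis: if the trial runs to completion under a stated assumption about the
still-unobserved data, what will the final confidence interval look like?
Observed data are combined with simulated future data and the end-of-trial
interval is computed; repeating this M times and plotting the replicate
intervals, ordered and brightness-coded by how central their point estimates
are, gives the predicted interval plot.

Two endpoint flavours are implemented:

* binary — future events are Binomial draws per arm; the final interval is
  the Wald interval for the difference in event proportions.  The reported
  difference is intervention minus control, so that benefit (fewer events on
  treatment) is negative and sits left of the null line at 0.
* survival — rather than simulating event times, the final logrank statistic
  is drawn directly from the B-value law B(1) = b + theta*(1-t) + N(0, 1-t),
  with the drift taken from the observed trend or a hypothesized hazard
  ratio, and the z-scale interval is back-transformed to the hazard-ratio
  scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.stats import gaussian_kde, norm

__all__ = [
    "BinaryTrialState",
    "SurvivalInterimState",
    "PIPResult",
    "binary_predicted_interval",
    "survival_predicted_final_z",
    "pip",
    "interval_width_reduction",
    "plot_pip",
]

#: Central percentile shells defining the four brightness bands, innermost
#: (brightest) first.
BRIGHTNESS_SHELLS = (0.50, 0.80, 0.95, 1.00)


@dataclass(frozen=True)
class BinaryTrialState:
    """Interim snapshot of a two-arm binary-endpoint trial.

    ``N_*`` are the target per-arm sample sizes, ``n_*`` the currently
    observed sample sizes, ``x_*`` the observed event counts, and ``pi_*``
    the assumed event probabilities for the not-yet-observed participants
    (the data-generating assumption: null, alternative, observed trend, ...).
    Subscripts c and i denote control and intervention.
    """

    N_c: int
    N_i: int
    n_c: int
    n_i: int
    x_c: int
    x_i: int
    pi_c: float
    pi_i: float

    def __post_init__(self) -> None:
        for arm in ("c", "i"):
            N, n, x = (getattr(self, f"{k}_{arm}") for k in ("N", "n", "x"))
            p = getattr(self, f"pi_{arm}")
            if not 0 <= x <= n <= N:
                raise ValueError(f"need 0 <= x <= n <= N in arm {arm!r}, got {x, n, N}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"event probability out of [0, 1] in arm {arm!r}: {p!r}")

    @classmethod
    def from_observed_trend(cls, N_c, N_i, n_c, n_i, x_c, x_i) -> "BinaryTrialState":
        """Future event probabilities set to the observed interim proportions."""
        return cls(N_c, N_i, n_c, n_i, x_c, x_i, pi_c=x_c / n_c, pi_i=x_i / n_i)


@dataclass(frozen=True)
class SurvivalInterimState:
    """Interim snapshot of a survival trial on the logrank z-score scale.

    ``d`` of the ``D`` targeted events have been observed, with logrank
    z-score ``z_interim`` (positive favours treatment).  ``hr_hypothesized``
    selects the drift assumption for the unobserved fraction: ``None`` uses
    the observed trend b/t, a hazard ratio uses the allocation-specific
    approximation |theta| = |ln HR| * sqrt(D/4) (1:1) or sqrt(2D/9) (2:1),
    oriented so HR < 1 (benefit) gives positive drift.
    """

    d: int
    D: int
    z_interim: float
    allocation: Literal["1:1", "2:1"] = "1:1"
    hr_hypothesized: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.d <= self.D:
            raise ValueError(f"need 0 < d <= D, got ({self.d}, {self.D})")
        if self.allocation not in ("1:1", "2:1"):
            raise ValueError(f"allocation must be '1:1' or '2:1', got {self.allocation!r}")
        if self.hr_hypothesized is not None and self.hr_hypothesized <= 0:
            raise ValueError("hazard ratio must be positive")

    @property
    def t(self) -> float:
        return self.d / self.D

    @property
    def b(self) -> float:
        return math.sqrt(self.t) * self.z_interim

    @property
    def drift_scale(self) -> float:
        """Multiplier c in |theta| = |ln HR| * c for this allocation."""
        if self.allocation == "1:1":
            return math.sqrt(self.D / 4.0)
        return math.sqrt(2.0 * self.D / 9.0)

    @property
    def theta(self) -> float:
        if self.hr_hypothesized is None:
            return self.b / self.t
        return -math.log(self.hr_hypothesized) * self.drift_scale


def binary_predicted_interval(
    state: BinaryTrialState,
    coverage: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float]:
    """One replicate predicted final interval for a binary endpoint.

    Simulates the unobserved participants as Binomial(N - n, pi) per arm,
    pools with the observed events into final proportions p_c, p_i, and
    returns ``(estimate, lower, upper)`` for the difference p_i - p_c with
    the Wald interval

        (p_i - p_c) +/- z_{alpha/2} * sqrt(p_c(1-p_c)/N_c + p_i(1-p_i)/N_i).

    With nothing left to observe (n = N) this is the ordinary Wald interval
    on the observed data.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage!r}")
    rng = np.random.default_rng(rng)
    fut_c = rng.binomial(state.N_c - state.n_c, state.pi_c)
    fut_i = rng.binomial(state.N_i - state.n_i, state.pi_i)
    p_c = (state.x_c + fut_c) / state.N_c
    p_i = (state.x_i + fut_i) / state.N_i
    est = p_i - p_c
    half = float(norm.ppf(0.5 + coverage / 2.0)) * math.sqrt(
        p_c * (1.0 - p_c) / state.N_c + p_i * (1.0 - p_i) / state.N_i
    )
    return est, est - half, est + half


@dataclass(frozen=True)
class SurvivalPrediction:
    """One replicate predicted end-of-trial result for a survival endpoint."""

    z_final: float
    z_lower: float
    z_upper: float
    hr: float
    hr_lower: float
    hr_upper: float


def survival_predicted_final_z(
    state: SurvivalInterimState,
    coverage: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> SurvivalPrediction:
    """One replicate predicted final logrank statistic and hazard-ratio interval.

    Draws B(1) = b + theta*(1-t) + N(0, sd = sqrt(1-t)); at t = 1 there is no
    noise and the observed value is returned.  The z-scale interval
    B(1) +/- z_{alpha/2} is mapped to hazard ratios by inverting
    theta = -ln(HR) * c, i.e. HR = exp(-z / c) at the targeted D events.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage!r}")
    rng = np.random.default_rng(rng)
    t, b = state.t, state.b
    if t >= 1.0:
        z1 = b
    else:
        z1 = b + state.theta * (1.0 - t) + rng.normal(0.0, math.sqrt(1.0 - t))
    zq = float(norm.ppf(0.5 + coverage / 2.0))
    z_lo, z_hi = z1 - zq, z1 + zq
    c = state.drift_scale
    # HR = exp(-z/c) is decreasing in z: the upper z limit gives the lower HR
    return SurvivalPrediction(
        z_final=z1, z_lower=z_lo, z_upper=z_hi,
        hr=math.exp(-z1 / c), hr_lower=math.exp(-z_hi / c), hr_upper=math.exp(-z_lo / c),
    )


@dataclass(frozen=True)
class PIPResult:
    """M replicate predicted intervals with brightness grouping and a summary.

    ``groups[r]`` is the brightness band of replicate r (1 = brightest, i.e.
    most central); ``summary`` is the (estimate, lower, upper) of the
    replicate at the median (percentile grouping) or at the kernel-density
    mode (cpdf grouping).
    """

    estimates: np.ndarray
    lowers: np.ndarray
    uppers: np.ndarray
    groups: np.ndarray
    summary: tuple[float, float, float]
    grouping: str
    seed: int | None

    @property
    def median_estimate(self) -> float:
        return float(np.median(self.estimates))

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.uppers - self.lowers))


def _group_percentile(estimates: np.ndarray) -> tuple[np.ndarray, int]:
    """Bands by central-percentile shells around the median; returns the
    per-replicate band and the index of the most central replicate."""
    dist = np.abs(estimates - np.median(estimates))
    ranks = np.argsort(np.argsort(dist, kind="stable"), kind="stable")
    frac = (ranks + 1) / len(estimates)
    groups = np.searchsorted(BRIGHTNESS_SHELLS, frac, side="left") + 1
    return groups.astype(int), int(np.argmin(dist))


def _group_cpdf(estimates: np.ndarray) -> tuple[np.ndarray, int]:
    """Bands by kernel-density height (Gaussian kernel, normal-reference
    bandwidth); the mode — the replicate with the highest density — is
    brightest."""
    if np.ptp(estimates) == 0.0:
        return np.ones(len(estimates), dtype=int), 0
    kde = gaussian_kde(estimates, bw_method="silverman")
    dens = kde(estimates)
    ranks = np.argsort(np.argsort(-dens, kind="stable"), kind="stable")
    frac = (ranks + 1) / len(estimates)
    groups = np.searchsorted(BRIGHTNESS_SHELLS, frac, side="left") + 1
    return groups.astype(int), int(np.argmax(dens))


def pip(
    generator: Callable[[np.random.Generator], tuple[float, float, float]],
    M: int = 500,
    grouping: Literal["percentile", "cpdf_mode"] = "percentile",
    rng_seed: int | None = None,
) -> PIPResult:
    """Run M replicate predicted intervals and group them for plotting.

    ``generator`` maps a random generator to one ``(estimate, lower, upper)``
    replicate — typically a closure over :func:`binary_predicted_interval`
    or :func:`survival_predicted_final_z`.
    """
    if M < 2:
        raise ValueError(f"need at least 2 replicates, got M={M}")
    if grouping not in ("percentile", "cpdf_mode"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(rng_seed)
    est = np.empty(M)
    lo = np.empty(M)
    hi = np.empty(M)
    for r in range(M):
        est[r], lo[r], hi[r] = generator(rng)
    if grouping == "percentile":
        groups, idx = _group_percentile(est)
    else:
        groups, idx = _group_cpdf(est)
    summary = (float(est[idx]), float(lo[idx]), float(hi[idx]))
    return PIPResult(est, lo, hi, groups, summary, grouping, rng_seed)


def interval_width_reduction(
    observed_interval: tuple[float, float], predicted_interval: tuple[float, float]
) -> float:
    """Fractional narrowing 1 - predicted_width / observed_width: the
    efficiency gained by continuing to full information."""
    ow = observed_interval[1] - observed_interval[0]
    pw = predicted_interval[1] - predicted_interval[0]
    if ow <= 0.0:
        raise ValueError("observed interval must have positive width")
    return 1.0 - pw / ow


def plot_pip(result: PIPResult, null_value: float = 0.0, ax=None, title: str | None = None):
    """Draw a predicted interval plot: replicate intervals as horizontal
    lines through their point estimates, sorted by estimate, brighter for
    more central replicates, with a vertical line at the null value."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    order = np.argsort(result.estimates)
    shade = {1: 0.95, 2: 0.65, 3: 0.40, 4: 0.18}
    for row, r in enumerate(order):
        alpha = shade.get(int(result.groups[r]), 0.18)
        ax.hlines(row, result.lowers[r], result.uppers[r], color="C0", alpha=alpha, lw=0.8)
        ax.plot(result.estimates[r], row, "o", color="C0", alpha=alpha, ms=2)
    ax.axvline(null_value, color="k", lw=1)
    ax.set_xlabel("treatment effect estimate")
    ax.set_ylabel("replicate (sorted)")
    if title:
        ax.set_title(title)
    return ax
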