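"""Spending functions, crossing probabilities, and boundary solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from futilitykit import (
    BoundarySet,
    InfeasibleSpendingError,
    LookSchedule,
    SpendingSpec,
    alpha_boundaries,
    beta_boundaries_and_drift,
    crossing_probabilities,
    simulate_paths,
    spend,
)
from futilitykit.simulate import _first_crossing_counts

OBF_UPPER_4 = (4.3326, 2.9631, 2.3590, 2.0141)


class TestSpend:
    def test_hsd_spends_total_at_end(self):
        spec = SpendingSpec("hsd_gamma", 0.15, gamma=-2)
        assert spend(spec, 1.0) == pytest.approx(0.15, abs=1e-12)

    def test_obf_spends_nothing_at_start(self):
        assert spend(SpendingSpec("obf_like", 0.15), 0.0) == 0.0

    def test_hsd_halfway_closed_form(self):
        spec = SpendingSpec("hsd_gamma", 0.15, gamma=-4)
        expected = 0.15 * (1 - math.exp(2)) / (1 - math.exp(4))
        assert spend(spec, 0.5) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0178, abs=1e-4)

    def test_hsd_gamma_zero_is_linear(self):
        spec = SpendingSpec("hsd_gamma", 0.15, gamma=0.0)
        assert spend(spec, 0.4) == pytest.approx(0.06, abs=1e-12)
        # continuity with small gamma
        near = SpendingSpec("hsd_gamma", 0.15, gamma=1e-8)
        assert spend(near, 0.4) == pytest.approx(0.06, abs=1e-6)

    def test_custom_tabulated(self):
        spec = SpendingSpec("custom", 0.1, table=((0, 0), (0.5, 0.02), (1, 0.1)))
        assert spend(spec, 0.25) == pytest.approx(0.01)
        assert spend(spec, 1.0) == pytest.approx(0.1)

    @pytest.mark.parametrize("family,gamma", [("obf_like", None), ("hsd_gamma", -4),
                                              ("hsd_gamma", 2)])
    def test_normalized_and_nondecreasing(self, family, gamma):
        spec = SpendingSpec(family, 0.15, gamma=gamma)
        grid = np.linspace(0, 1, 101)
        vals = [spend(spec, t) for t in grid]
        assert vals[0] == 0.0
        assert vals[-1] == pytest.approx(0.15, abs=1e-10)
        assert all(b >= a - 1e-14 for a, b in zip(vals, vals[1:]))

    def test_rejects_out_of_range_time(self):
        with pytest.raises(ValueError):
            spend(SpendingSpec("obf_like", 0.1), 1.2)


class TestCrossingProbabilities:
    def test_single_look_lower_closed_form(self):
        theta = 3.2416
        bounds = BoundarySet(LookSchedule([1.0]), (1.96,), (1.96,))
        res = crossing_probabilities(bounds, theta)
        assert res.fcp_lower[0] == pytest.approx(norm.cdf(1.96 - theta), abs=1e-10)
        assert res.fcp_lower[0] == pytest.approx(0.100, abs=5e-4)
        assert res.p_continue == pytest.approx(0.0, abs=1e-12)

    def test_single_look_one_sided_alpha(self):
        bounds = BoundarySet(LookSchedule([1.0]), (-np.inf,), (1.96,))
        res = crossing_probabilities(bounds, 0.0)
        assert res.fcp_upper[0] == pytest.approx(norm.sf(1.96), abs=1e-12)

    def test_alpha_spending_conserves_total_alpha(self, four_looks):
        upper = alpha_boundaries(four_looks, SpendingSpec("obf_like", 0.025))
        bounds = BoundarySet(four_looks, (-np.inf,) * 4, upper)
        res = crossing_probabilities(bounds, 0.0)
        assert res.total_upper == pytest.approx(0.025, abs=1e-4)

    def test_probabilities_partition_unity(self, four_looks):
        bounds = BoundarySet(four_looks, (-0.5, 0.0, 0.5, 1.96), (3.5, 3.0, 2.5, 1.96))
        for theta in (0.0, 1.5, 3.0):
            res = crossing_probabilities(bounds, theta)
            total = res.total_lower + res.total_upper + res.p_continue
            assert total == pytest.approx(1.0, abs=1e-8)
            assert all(p >= 0 for p in res.fcp_lower + res.fcp_upper)

    def test_cumulative_totals_invariant_to_free_extra_look(self):
        sched3 = LookSchedule([0.3, 0.6, 1.0])
        sched4 = LookSchedule([0.3, 0.6, 0.8, 1.0])
        b3 = BoundarySet(sched3, (-1.0, 0.0, 1.96), (np.inf, np.inf, 1.96))
        b4 = BoundarySet(sched4, (-1.0, 0.0, -np.inf, 1.96),
                         (np.inf, np.inf, np.inf, 1.96))
        r3 = crossing_probabilities(b3, 2.5)
        r4 = crossing_probabilities(b4, 2.5)
        assert r3.fcp_lower[:2] == pytest.approx(r4.fcp_lower[:2], abs=1e-10)
        assert r3.total_lower == pytest.approx(r4.total_lower, abs=1e-8)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            LookSchedule([])

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_agrees_with_monte_carlo_oracle(self, seed):
        """Randomized small designs: integration within 3 SE of 2e5 paths."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        times = np.sort(rng.uniform(0.1, 0.95, size=k - 1)).tolist() + [1.0]
        sched = LookSchedule(times)
        theta = float(rng.uniform(0, 3.5))
        lower = np.sort(rng.uniform(-2, 1.5, size=k))
        upper = lower + rng.uniform(0.5, 3.0, size=k)
        lower[-1] = upper[-1] = 1.96
        bounds = BoundarySet(sched, tuple(lower), tuple(upper))
        exact = crossing_probabilities(bounds, theta)
        batch = simulate_paths(sched, theta, 200_000, seed=seed)
        low, up, alive = _first_crossing_counts(
            batch.z_matrix, np.asarray(lower), np.asarray(upper)
        )
        n = batch.n_rep
        for p_exact, count in [(exact.total_lower, low.sum()), (exact.total_upper, up.sum())]:
            p_emp = count / n
            se = math.sqrt(max(p_emp * (1 - p_emp), 1e-12) / n)
            assert abs(p_exact - p_emp) <= 3 * se


class TestAlphaBoundaries:
    def test_reproduces_obf_four_look_values(self, four_looks):
        upper = alpha_boundaries(four_looks, SpendingSpec("obf_like", 0.025))
        assert upper == pytest.approx(OBF_UPPER_4, abs=5e-5)

    def test_single_look_is_normal_quantile(self):
        upper = alpha_boundaries(LookSchedule([1.0]), SpendingSpec("obf_like", 0.025))
        assert upper[0] == pytest.approx(1.9600, abs=5e-5)

    def test_round_trip_cumulative_spend(self):
        sched = LookSchedule([0.5, 1.0])
        spec = SpendingSpec("obf_like", 0.025)
        upper = alpha_boundaries(sched, spec)
        res = crossing_probabilities(
            BoundarySet(sched, (-np.inf, -np.inf), upper), 0.0
        )
        cum = np.cumsum(res.fcp_upper)
        for t, c in zip(sched.times, cum):
            assert c == pytest.approx(spend(spec, t), abs=1e-6)

    def test_zero_increment_gives_infinite_boundary(self):
        spec = SpendingSpec("custom", 0.025, table=((0, 0), (0.5, 0.0), (1, 0.025)))
        upper = alpha_boundaries(LookSchedule([0.5, 1.0]), spec)
        assert np.isinf(upper[0])
        assert upper[1] == pytest.approx(1.9600, abs=5e-5)


@pytest.fixture(scope="module")
def obf_upper():
    return alpha_boundaries(LookSchedule.equally_spaced(4),
                            SpendingSpec("obf_like", 0.025))


class TestBetaBoundariesAndDrift:
    @pytest.mark.parametrize(
        "gamma, lower_expected, drift_expected",
        [
            (-4, (-1.0607, -0.0037, 0.9761, 2.0141), 3.0572),
            (2, (0.2788, 1.0364, 1.5654, 2.0141), 3.5353),
        ],
    )
    def test_published_four_look_rows(self, obf_upper, gamma, lower_expected,
                                      drift_expected):
        # agreement within 1.5 units in the 4th decimal; the residual traces
        # to the reference values' finite drift-grid search
        sched = LookSchedule.equally_spaced(4)
        res = beta_boundaries_and_drift(
            sched, SpendingSpec("hsd_gamma", 0.15, gamma=gamma), obf_upper
        )
        assert res.bounds.lower == pytest.approx(lower_expected, abs=1.5e-4)
        assert res.theta == pytest.approx(drift_expected, abs=1.5e-4)
        assert res.total_type2 == pytest.approx(0.15, abs=1e-5)

    def test_spending_increments_achieved(self, obf_upper):
        sched = LookSchedule.equally_spaced(4)
        spec = SpendingSpec("hsd_gamma", 0.15, gamma=-2)
        res = beta_boundaries_and_drift(sched, spec, obf_upper)
        probs = crossing_probabilities(res.bounds, res.theta)
        cum = [spend(spec, t) for t in sched.times]
        incs = np.diff([0.0] + cum)
        for j in range(3):
            assert probs.fcp_lower[j] == pytest.approx(incs[j], abs=1e-5)
        assert probs.total_lower == pytest.approx(0.15, abs=1e-5)

    def test_final_boundaries_coincide(self, obf_upper):
        res = beta_boundaries_and_drift(
            LookSchedule.equally_spaced(4),
            SpendingSpec("hsd_gamma", 0.15, gamma=-4), obf_upper,
        )
        assert res.bounds.lower[-1] == res.bounds.upper[-1]

    def test_lower_boundaries_nondecreasing(self, obf_upper):
        for gamma in (-4, -2, 2):
            res = beta_boundaries_and_drift(
                LookSchedule.equally_spaced(4),
                SpendingSpec("hsd_gamma", 0.15, gamma=gamma), obf_upper,
            )
            lows = res.bounds.lower
            assert all(b > a for a, b in zip(lows, lows[1:]))

    def test_conservative_drift_barely_exceeds_no_monitoring(self, obf_upper):
        res = beta_boundaries_and_drift(
            LookSchedule.equally_spaced(4),
            SpendingSpec("hsd_gamma", 0.15, gamma=-4), obf_upper,
        )
        no_monitoring = 3.00  # 85% power, one-sided alpha 0.025
        assert no_monitoring < res.theta < no_monitoring + 0.1

    def test_sample_size_inflation_ratio(self, obf_upper):
        sched = LookSchedule.equally_spaced(4)
        cons = beta_boundaries_and_drift(
            sched, SpendingSpec("hsd_gamma", 0.15, gamma=-4), obf_upper).theta
        aggr = beta_boundaries_and_drift(
            sched, SpendingSpec("hsd_gamma", 0.15, gamma=2), obf_upper).theta
        assert (aggr / cons) ** 2 == pytest.approx(1.337, abs=5e-3)

    def test_empirical_type2_matches_solved_boundaries(self, obf_upper):
        res = beta_boundaries_and_drift(
            LookSchedule.equally_spaced(4),
            SpendingSpec("hsd_gamma", 0.15, gamma=-4), obf_upper,
        )
        batch = simulate_paths(res.bounds.schedule, res.theta, 200_000, seed=7)
        low, _, _ = _first_crossing_counts(
            batch.z_matrix, np.asarray(res.bounds.lower), np.asarray(res.bounds.upper)
        )
        p = low.sum() / batch.n_rep
        se = math.sqrt(p * (1 - p) / batch.n_rep)
        assert abs(p - 0.15) <= 3 * se

    def test_infeasible_spending_raises_with_diagnostic(self):
        # demand nearly all beta at a tiny first look against a binding drift
        sched = LookSchedule([0.05, 1.0])
        spec = SpendingSpec("custom", 0.15, table=((0, 0), (0.05, 0.1499), (1, 0.15)))
        upper = (1.96, 1.96)
        with pytest.raises(ValueError, match="bracket|infeasible"):
            beta_boundaries_and_drift(sched, spec, upper, theta_bracket=(0.0, 0.5))
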