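"""Cohort engine: propagation, conservation, discounting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mddcea import (
    RewardModel,
    StateSpace,
    TransitionModel,
    check_stochastic,
    discounted_totals,
    run_cohort,
)

TWO = StateSpace(states=("alive", "death"), absorbing=frozenset({"death"}))


def two_state_model(p_death: float) -> TransitionModel:
    m = np.array([[1 - p_death, p_death], [0.0, 1.0]])
    return TransitionModel.homogeneous_from(TWO, m)


class TestCheckStochastic:
    def test_identity_clean(self):
        assert check_stochastic(np.eye(3)) == []

    def test_row_sum_violation_names_row(self):
        m = np.array([[0.5, 0.4], [0.0, 1.0]])
        bad = check_stochastic(m, labels=["alive", "dead"])
        assert len(bad) == 1 and "alive" in bad[0]

    def test_negative_entry_flagged(self):
        m = np.array([[1.1, -0.1], [0.0, 1.0]])
        bad = check_stochastic(m)
        assert any("negative probability" in v for v in bad)

    def test_non_square_rejected(self):
        assert check_stochastic(np.ones((2, 3))) != []


class TestRunCohort:
    def test_identity_transitions_freeze_occupancy(self):
        tm = TransitionModel.homogeneous_from(TWO, np.eye(2))
        trace = run_cohort(tm, [0.7, 0.3], horizon=5)
        assert np.allclose(trace.occupancy, [[0.7, 0.3]] * 6)

    def test_geometric_survival(self):
        trace = run_cohort(two_state_model(0.1), [1.0, 0.0], horizon=30)
        expected = 0.9 ** np.arange(31)
        assert np.allclose(trace.column("alive"), expected, atol=1e-12)

    def test_death_column_non_decreasing(self):
        trace = run_cohort(two_state_model(0.07), [1.0, 0.0], horizon=40)
        assert np.all(np.diff(trace.column("death")) >= -1e-12)

    def test_bad_initial_rejected(self):
        tm = two_state_model(0.1)
        with pytest.raises(ValueError):
            run_cohort(tm, [0.7, 0.7], horizon=3)
        with pytest.raises(ValueError):
            run_cohort(tm, [1.0, 0.0], horizon=0)

    def test_non_stochastic_matrix_reported_with_cycle(self):
        space = StateSpace(states=("a", "b"))
        tm = TransitionModel(space, lambda t: np.eye(2) * (1.0 if t < 2 else 0.9))
        with pytest.raises(ValueError, match="cycle 2"):
            run_cohort(tm, [1.0, 0.0], horizon=5)

    def test_absorbing_state_must_self_loop(self):
        m = np.array([[0.9, 0.1], [0.5, 0.5]])
        with pytest.raises(ValueError, match="absorbing"):
            TransitionModel.homogeneous_from(TWO, m)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=6))
def test_mass_conserved_for_random_stochastic_matrices(seed, n_states):
    rng = np.random.default_rng(seed)
    m = rng.dirichlet(np.ones(n_states), size=n_states)
    space = StateSpace(states=tuple(f"s{i}" for i in range(n_states)))
    trace = run_cohort(TransitionModel.homogeneous_from(space, m),
                       np.eye(n_states)[0], horizon=25)
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
    assert trace.occupancy.min() >= -1e-12


class TestDiscountedTotals:
    def test_undiscounted_single_state_sum(self):
        space = StateSpace(states=("alive",))
        tm = TransitionModel.homogeneous_from(space, np.eye(1))
        rm = RewardModel.from_vectors(space, [100.0], [0.8])
        trace = run_cohort(tm, [1.0], horizon=10)
        out = discounted_totals(trace, rm, rate=0.0)
        assert out.cost == pytest.approx(1000.0)
        assert out.qaly == pytest.approx(8.0)

    def test_geometric_series_closed_form(self):
        # survival 0.9/cycle, $100 & 0.8 utility per alive-year, 3%/yr discount:
        # lifetime cost -> 100 / (1 - 0.9/1.03) = 792.3077; QALY = 0.008 x that
        rm = RewardModel.from_vectors(TWO, [100.0, 0.0], [0.8, 0.0])
        trace = run_cohort(two_state_model(0.1), [1.0, 0.0], horizon=2000)
        out = discounted_totals(trace, rm, rate=0.03)
        expected_cost = 100.0 / (1.0 - 0.9 / 1.03)
        assert out.cost == pytest.approx(expected_cost, rel=1e-9)
        assert out.qaly == pytest.approx(0.008 * expected_cost, rel=1e-9)

    @pytest.mark.parametrize("p_death,horizon,rate", [
        (0.25, 12, 0.0), (0.1, 40, 0.03), (0.02, 60, 0.07),
    ])
    def test_finite_horizon_matches_explicit_sum(self, p_death, horizon, rate):
        """Engine totals equal the closed-form finite geometric sum."""
        rm = RewardModel.from_vectors(TWO, [57.0, 0.0], [0.63, 0.0])
        trace = run_cohort(two_state_model(p_death), [1.0, 0.0], horizon=horizon)
        out = discounted_totals(trace, rm, rate=rate)
        q = (1 - p_death) / (1 + rate)
        geo = (horizon if q == 1 else (1 - q ** horizon) / (1 - q))
        assert out.cost == pytest.approx(57.0 * geo, rel=1e-12)
        assert out.qaly == pytest.approx(0.63 * geo, rel=1e-12)

    def test_all_dead_cohort_accrues_nothing(self):
        rm = RewardModel.from_vectors(TWO, [100.0, 0.0], [0.8, 0.0])
        trace = run_cohort(two_state_model(0.5), [0.0, 1.0], horizon=10)
        out = discounted_totals(trace, rm, rate=0.03)
        assert out.cost == 0.0 and out.qaly == 0.0

    def test_negative_rate_rejected(self):
        rm = RewardModel.from_vectors(TWO, [1.0, 0.0], [0.5, 0.0])
        trace = run_cohort(two_state_model(0.1), [1.0, 0.0], horizon=2)
        with pytest.raises(ValueError):
            discounted_totals(trace, rm, rate=-0.01)

    def test_cost_monotone_in_horizon_and_rate(self):
        rm = RewardModel.from_vectors(TWO, [100.0, 0.0], [0.8, 0.0])
        tm = two_state_model(0.1)
        costs_by_horizon = [
            discounted_totals(run_cohort(tm, [1.0, 0.0], h), rm, 0.03).cost
            for h in (5, 10, 20, 40)
        ]
        assert costs_by_horizon == sorted(costs_by_horizon)
        trace = run_cohort(tm, [1.0, 0.0], 40)
        costs_by_rate = [discounted_totals(trace, rm, r).cost
                         for r in (0.0, 0.03, 0.1, 0.5)]
        assert costs_by_rate == sorted(costs_by_rate, reverse=True)

    def test_half_cycle_correction_averages_endpoints(self):
        rm = RewardModel.from_vectors(TWO, [100.0, 0.0], [1.0, 0.0])
        trace = run_cohort(two_state_model(0.2), [1.0, 0.0], horizon=3)
        plain = discounted_totals(trace, rm, rate=0.0)
        half = discounted_totals(trace, rm, rate=0.0, half_cycle_correction=True)
        alive = 0.8 ** np.arange(4)
        assert plain.cost == pytest.approx(100 * alive[:3].sum())
        assert half.cost == pytest.approx(100 * (0.5 * (alive[:3] + alive[1:])).sum())


def test_trace_frame_reports_discounted_stage_values():
    rm = RewardModel.from_vectors(TWO, [100.0, 0.0], [0.8, 0.0])
    trace = run_cohort(two_state_model(0.1), [1.0, 0.0], horizon=4)
    df = trace.to_frame(rm, rate=0.03)
    assert set(df.columns) == {"cycle", "state", "occupancy", "cycle_cost_usd",
                              "cycle_qaly", "discounted_cost_usd", "discounted_qaly"}
    row = df[(df.cycle == 2) & (df.state == "alive")].iloc[0]
    assert row.occupancy == pytest.approx(0.81)
    assert row.discounted_cost_usd == pytest.approx(0.81 * 100 / 1.03**2)
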