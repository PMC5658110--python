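"""Discrete-time cohort Markov engine.

The engine is deliberately generic: a :class:`StateSpace` names the states,
a :class:`TransitionModel` supplies a row-stochastic matrix per cycle, a
:class:`RewardModel` prices each state in USD/cycle and Euro-QoL utility per
cycle, and :func:`run_cohort` propagates a unit cohort forward.  Discounted
lifetime totals follow the standard convention 1/(1+r)^t with cycle 0
undiscounted; rewards accrue on start-of-cycle occupancy unless half-cycle
correction is requested, in which case the mean of start and end occupancy
is used.

The cycle length is one year throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import StrategyOutcome

STOCHASTIC_TOL = 1e-9  # absolute per-row tolerance; double-precision safe


@dataclass(frozen=True)
class StateSpace:
    states: tuple[str, ...]
    absorbing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))
        if len(set(self.states)) != len(self.states):
            raise ValueError("state identifiers must be unique")
        if not self.absorbing <= set(self.states):
            raise ValueError("absorbing states must be a subset of states")

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)


def check_stochastic(matrix: np.ndarray, labels: Optional[Sequence[str]] = None,
                     tol: float = STOCHASTIC_TOL) -> list[str]:
    """Report every way ``matrix`` fails to be row-stochastic.

    Empty list iff all entries lie in [0, 1] and every row sums to 1 within
    ``tol``.  Violations name the offending row.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        return [f"matrix is not square: shape {m.shape}"]
    # vectorized clean path; fall through to the row loop only on failure
    if (m.min() >= -tol and m.max() <= 1 + tol
            and np.abs(m.sum(axis=1) - 1.0).max() <= tol):
        return []
    names = list(labels) if labels is not None else [f"row {i}" for i in range(m.shape[0])]
    out: list[str] = []
    for i in range(m.shape[0]):
        row = m[i]
        if np.any(row < -tol):
            out.append(f"{names[i]}: negative probability {row.min():.3g}")
        if np.any(row > 1 + tol):
            out.append(f"{names[i]}: probability exceeds 1 ({row.max():.3g})")
        s = row.sum()
        if abs(s - 1.0) > tol:
            out.append(f"{names[i]}: row sums to {s!r}, not 1")
    return out


class TransitionModel:
    """Cycle-indexed transition structure over a state space.

    Most models here are time-homogeneous; construct those with
    :meth:`homogeneous` so the single matrix is validated once.  The general
    form takes ``matrix_fn(cycle) -> (S, S) array``.
    """

    def __init__(self, state_space: StateSpace,
                 matrix_fn: Callable[[int], np.ndarray],
                 homogeneous: bool = False) -> None:
        self.state_space = state_space
        self._matrix_fn = matrix_fn
        self.homogeneous = homogeneous
        self._cached: Optional[np.ndarray] = None

    @classmethod
    def homogeneous_from(cls, state_space: StateSpace, matrix: np.ndarray) -> "TransitionModel":
        m = np.asarray(matrix, dtype=float)
        tm = cls(state_space, lambda _t: m, homogeneous=True)
        tm._validate(m, cycle=0)
        tm._cached = m
        return tm

    def _validate(self, m: np.ndarray, cycle: int) -> None:
        bad = check_stochastic(m, labels=self.state_space.states)
        if bad:
            raise ValueError(f"non-stochastic transition matrix at cycle {cycle}: " + "; ".join(bad))
        for s in self.state_space.absorbing:
            i = self.state_space.index(s)
            if abs(m[i, i] - 1.0) > STOCHASTIC_TOL:
                raise ValueError(f"absorbing state {s!r} must self-transition with probability 1")

    def transition(self, cycle: int) -> np.ndarray:
        if self.homogeneous and self._cached is not None:
            return self._cached
        m = np.asarray(self._matrix_fn(cycle), dtype=float)
        self._validate(m, cycle)
        return m


class RewardModel:
    """Per-state, per-cycle cost (USD/year) and utility (Euro-QoL/year).

    Utility of any state named ``death`` is forced to 0; costs must be
    non-negative.  Stationary rewards (the common case) are held as vectors
    aligned with the state space.
    """

    def __init__(self, state_space: StateSpace,
                 cost: Callable[[str, int], float],
                 utility: Callable[[str, int], float]) -> None:
        self.state_space = state_space
        self._cost_fn = cost
        self._utility_fn = utility
        self._stationary: Optional[tuple[np.ndarray, np.ndarray]] = None

    @classmethod
    def from_vectors(cls, state_space: StateSpace,
                     cost: Sequence[float], utility: Sequence[float]) -> "RewardModel":
        c = np.asarray(cost, dtype=float)
        u = np.asarray(utility, dtype=float)
        if c.shape != (len(state_space),) or u.shape != (len(state_space),):
            raise ValueError("reward vectors must align with the state space")
        if np.any(c < 0):
            raise ValueError("costs must be non-negative")
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("utilities must lie in [0, 1]")
        for i, s in enumerate(state_space.states):
            if s == "death" and u[i] != 0.0:
                raise ValueError("utility of death must be 0")
        rm = cls(state_space, lambda s, _t: c[state_space.index(s)],
                 lambda s, _t: u[state_space.index(s)])
        rm._stationary = (c, u)
        return rm

    def cost(self, state: str, cycle: int) -> float:
        return float(self._cost_fn(state, cycle))

    def utility(self, state: str, cycle: int) -> float:
        if state == "death":
            return 0.0
        return float(self._utility_fn(state, cycle))

    def reward_matrices(self, horizon: int) -> tuple[np.ndarray, np.ndarray]:
        """(horizon, S) cost and utility arrays for cycles 0..horizon-1."""
        if self._stationary is not None:
            c, u = self._stationary
            return (np.broadcast_to(c, (horizon, len(c))),
                    np.broadcast_to(u, (horizon, len(u))))
        states = self.state_space.states
        c = np.array([[self.cost(s, t) for s in states] for t in range(horizon)])
        u = np.array([[self.utility(s, t) for s in states] for t in range(horizon)])
        return c, u


@dataclass
class CohortTrace:
    """Occupancy of each health state per cycle for a unit cohort.

    ``occupancy`` has one row per cycle 0..T (T+1 rows) and one column per
    state; every row sums to 1.
    """

    state_space: StateSpace
    occupancy: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def column(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.state_space.index(state)]

    def to_frame(self, rm: Optional[RewardModel] = None,
                 rate: float = 0.0) -> pd.DataFrame:
        """Long-format stage table: one row per (cycle, state).

        With a reward model, adds per-cycle cost/QALY contributions and their
        discounted variants, mirroring a per-stage audit table.
        """
        rows = []
        for t in range(self.occupancy.shape[0]):
            disc = (1.0 + rate) ** (-t)
            for j, s in enumerate(self.state_space.states):
                occ = self.occupancy[t, j]
                row = {"cycle": t, "state": s, "occupancy": occ}
                if rm is not None:
                    row["cycle_cost_usd"] = occ * rm.cost(s, t)
                    row["cycle_qaly"] = occ * rm.utility(s, t)
                    row["discounted_cost_usd"] = row["cycle_cost_usd"] * disc
                    row["discounted_qaly"] = row["cycle_qaly"] * disc
                rows.append(row)
        return pd.DataFrame(rows)


def run_cohort(tm: TransitionModel, initial: Sequence[float], horizon: int) -> CohortTrace:
    """Propagate a cohort: row t+1 = row t @ transition(t), cycles 0..horizon."""
    x0 = np.asarray(initial, dtype=float)
    n = len(tm.state_space)
    if x0.shape != (n,):
        raise ValueError(f"initial occupancy must have length {n}")
    if abs(x0.sum() - 1.0) > STOCHASTIC_TOL or np.any(x0 < 0):
        raise ValueError("initial occupancy must be a distribution summing to 1")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    occ = np.empty((horizon + 1, n))
    occ[0] = x0
    if tm.homogeneous:
        m = tm.transition(0)
        for t in range(horizon):
            occ[t + 1] = occ[t] @ m
    else:
        for t in range(horizon):
            occ[t + 1] = occ[t] @ tm.transition(t)
    return CohortTrace(state_space=tm.state_space, occupancy=occ)


def discounted_totals(trace: CohortTrace, rm: RewardModel, rate: float,
                      half_cycle_correction: bool = False,
                      label: str = "") -> StrategyOutcome:
    """Discounted lifetime cost and QALYs of a trace under a reward model.

    cost = sum_t sum_s occ[t, s] * cost(s, t) / (1+rate)^t over cycles
    0..T-1 (rewards accrue at cycle start), and analogously for QALYs.  With
    half-cycle correction, occ[t] is replaced by (occ[t] + occ[t+1]) / 2.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if trace.state_space.states != rm.state_space.states:
        raise ValueError("trace and reward model must share a state space")
    horizon = trace.horizon
    occ = trace.occupancy[:horizon]
    if half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:horizon] + trace.occupancy[1:horizon + 1])
    c, u = rm.reward_matrices(horizon)
    disc = (1.0 + rate) ** (-np.arange(horizon))
    cost = float(np.einsum("t,ts,ts->", disc, occ, c))
    qaly = float(np.einsum("t,ts,ts->", disc, occ, u))
    return StrategyOutcome(label=label, cost=cost, qaly=qaly)
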