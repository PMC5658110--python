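"""Strategy models for the two treatment arms.

Each arm (rTMS or continued antidepressant pharmacotherapy, entered after a
single failed medication trial) is expanded into an attempt-indexed annual
state space:

    in_treatment(1..K)  active treatment attempt k with the arm's therapy
    response_maintenance  responded without remitting; maintained, lower utility
    remission_maintenance remitted; maintenance medication + psychotherapy
    relapse               lost response/remission; re-treated next cycle
    ect                   fallback after K failed attempts (K = 4 by default)
    death                 absorbing

The probability of succeeding on attempt k is the first-attempt probability
attenuated multiplicatively per prior failure — success diminishes with each
unsuccessful trial.  Background mortality is an annual hazard of
1/likely-life-expectancy applied first each cycle as a competing risk, with
the clinical transitions renormalized over survivors; the hard stop is the
cohort's horizon in annual cycles.

Costs per state-year combine Medicare-style unit rates: an rTMS treatment
year bills the initial motor-threshold session plus subsequent sessions plus
periodic motor-threshold re-determinations; a pharmacotherapy treatment year
bills twelve months of drug supply; both add psychotherapy and the
non-depression direct medical costs common to every alive state.
Maintenance (response or remission) and relapse years carry maintenance
medication plus psychotherapy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .economics import StrategyOutcome, ComparisonResult, icer
from .markov_engine import (
    RewardModel,
    StateSpace,
    TransitionModel,
    discounted_totals,
    run_cohort,
)
from .params_io import LifeExpectancy, ParameterSet

RTMS = "rTMS"
PHARMA = "pharmacotherapy"
STRATEGIES = (RTMS, PHARMA)

_ARM_SUFFIX = {RTMS: "rtms", PHARMA: "pharma"}


@dataclass(frozen=True)
class StrategySpec:
    label: str
    max_attempts: int = 4

    def __post_init__(self) -> None:
        if self.label not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.label!r}")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def build_state_space(spec: StrategySpec) -> StateSpace:
    """Attempt-expanded state space; ordering is stable across calls."""
    states = tuple(f"in_treatment_{k}" for k in range(1, spec.max_attempts + 1)) + (
        "response_maintenance",
        "remission_maintenance",
        "relapse",
        "ect",
        "death",
    )
    return StateSpace(states=states, absorbing=frozenset({"death"}))


def attempt_success_probability(base: float,
                                attempt: int,
                                attenuation: Union[float, Sequence[float]]) -> float:
    """Success probability on the k-th attempt of the same therapy.

    ``base * attenuation**(attempt-1)``, clamped to [0, 1].  ``attenuation``
    may be a per-attempt vector, in which case the factors for attempts
    2..k are multiplied (entry j applies after the j-th failure; the vector
    is right-padded with its last value).
    """
    if not 0.0 <= base <= 1.0:
        raise ValueError("base probability must lie in [0, 1]")
    if attempt < 1:
        raise ValueError("attempt index starts at 1")
    if np.isscalar(attenuation):
        a = float(attenuation)  # type: ignore[arg-type]
        if not 0.0 <= a <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        p = base * a ** (attempt - 1)
    else:
        factors = list(attenuation)  # type: ignore[arg-type]
        if any(not 0.0 <= f <= 1.0 for f in factors):
            raise ValueError("attenuation factors must lie in [0, 1]")
        p = base
        for j in range(attempt - 1):
            p *= factors[min(j, len(factors) - 1)]
    return min(max(p, 0.0), 1.0)


@dataclass(frozen=True)
class ClinicalProbabilities:
    base_remission: float
    base_response: float
    attenuation: float
    relapse_annual: float
    ect_remission: float
    death: float  # annual background mortality hazard

    @classmethod
    def from_parameter_set(cls, ps: ParameterSet, label: str) -> "ClinicalProbabilities":
        arm = _ARM_SUFFIX[label]
        death = (1.0 / ps.life_expectancy.likely
                 if ps.options.include_background_mortality else 0.0)
        return cls(
            base_remission=ps.value(f"p_remission_{arm}"),
            base_response=ps.value(f"p_response_{arm}"),
            attenuation=ps.value(f"attenuation_{arm}"),
            relapse_annual=ps.value(f"relapse_annual_{arm}"),
            ect_remission=ps.value("p_remission_ect"),
            death=death,
        )


@dataclass(frozen=True)
class CostInputs:
    rtms_session_rate: float            # CPT 90868, USD/session
    rtms_initial_rate: float            # CPT 90867, USD (first session incl. motor threshold)
    rtms_mt_redetermination_rate: float  # CPT 90869, USD
    rtms_sessions_per_year: float
    rtms_mt_redeterminations_per_year: float
    drug_monthly: float                 # USD/month antidepressant supply
    psychotherapy_session_rate: float
    psychotherapy_sessions_per_year: float
    ect_course_cost: float              # USD per year in the ECT state
    other_direct_annual: float          # inpatient/outpatient/ED, USD/year

    @classmethod
    def from_parameter_set(cls, ps: ParameterSet) -> "CostInputs":
        return cls(
            rtms_session_rate=ps.value("cost_per_rtms_session"),
            rtms_initial_rate=ps.value("cost_rtms_initial_session"),
            rtms_mt_redetermination_rate=ps.value("cost_rtms_mt_redetermination"),
            rtms_sessions_per_year=ps.value("rtms_sessions_per_year"),
            rtms_mt_redeterminations_per_year=ps.value("rtms_mt_redeterminations_per_year"),
            drug_monthly=ps.value("drug_cost_monthly"),
            psychotherapy_session_rate=ps.value("psychotherapy_session_rate"),
            psychotherapy_sessions_per_year=ps.value("psychotherapy_sessions_per_year"),
            ect_course_cost=ps.value("ect_course_cost_annual"),
            other_direct_annual=ps.value("other_direct_annual"),
        )


@dataclass(frozen=True)
class UtilityInputs:
    in_treatment: float
    nonresponse: float
    response: float
    remission_maintenance: float
    relapse: float
    ect: float
    # death is fixed at 0 by the engine

    @classmethod
    def from_parameter_set(cls, ps: ParameterSet) -> "UtilityInputs":
        return cls(
            in_treatment=ps.value("utility_in_treatment"),
            nonresponse=ps.value("utility_nonresponse"),
            response=ps.value("utility_response"),
            remission_maintenance=ps.value("utility_remission"),
            relapse=ps.value("utility_relapse"),
            ect=ps.value("utility_ect"),
        )


def annual_treatment_cost(spec: StrategySpec, state: str, costs: CostInputs) -> float:
    """USD per year accrued by one patient-year in ``state`` under ``spec``.

    An rTMS treatment year: one initial session (CPT 90867), the remaining
    sessions at the repeat rate (CPT 90868), motor-threshold
    re-determinations (CPT 90869), psychotherapy, and other direct costs.
    A pharmacotherapy treatment year: 12 months of drug supply plus
    psychotherapy and other direct costs.  Maintenance and relapse years:
    maintenance antidepressants plus psychotherapy plus other direct costs.
    The ECT year: the annual course cost plus other direct costs.
    """
    psych = costs.psychotherapy_session_rate * costs.psychotherapy_sessions_per_year
    maintenance_meds = 12.0 * costs.drug_monthly
    if state.startswith("in_treatment"):
        if spec.label == RTMS:
            sessions = max(costs.rtms_sessions_per_year - 1.0, 0.0)
            return (costs.rtms_initial_rate
                    + sessions * costs.rtms_session_rate
                    + costs.rtms_mt_redeterminations_per_year * costs.rtms_mt_redetermination_rate
                    + psych + costs.other_direct_annual)
        return maintenance_meds + psych + costs.other_direct_annual
    if state in ("response_maintenance", "remission_maintenance", "relapse"):
        return maintenance_meds + psych + costs.other_direct_annual
    if state == "ect":
        return costs.ect_course_cost + costs.other_direct_annual
    if state == "death":
        return 0.0
    raise ValueError(f"unknown state {state!r} for strategy {spec.label}")


def state_utility(state: str, u: UtilityInputs) -> float:
    """Euro-QoL utility of a model state; attempts after the first carry the
    non-response utility (the patient has already failed on this arm)."""
    if state == "in_treatment_1":
        return u.in_treatment
    if state.startswith("in_treatment"):
        return u.nonresponse
    mapping = {
        "response_maintenance": u.response,
        "remission_maintenance": u.remission_maintenance,
        "relapse": u.relapse,
        "ect": u.ect,
        "death": 0.0,
    }
    try:
        return mapping[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}") from None


def build_transition_matrix(spec: StrategySpec, probs: ClinicalProbabilities,
                            reentry_attempt: int = 1) -> np.ndarray:
    """Annual transition matrix for one arm (time-homogeneous).

    Background mortality ``probs.death`` is applied first; the clinical
    transitions share the surviving mass ``1 - death``.
    """
    space = build_state_space(spec)
    n = len(space)
    idx = {s: i for i, s in enumerate(space.states)}
    d = probs.death
    if not 0.0 <= d <= 1.0:
        raise ValueError("death probability must lie in [0, 1]")
    alive = 1.0 - d
    m = np.zeros((n, n))
    k_max = spec.max_attempts
    if not 1 <= reentry_attempt <= k_max:
        raise ValueError("relapse re-entry attempt must lie in 1..max_attempts")
    for k in range(1, k_max + 1):
        i = idx[f"in_treatment_{k}"]
        p_rem = attempt_success_probability(probs.base_remission, k, probs.attenuation)
        p_res = attempt_success_probability(probs.base_response, k, probs.attenuation)
        if p_rem + p_res > 1.0 + 1e-12:
            raise ValueError(
                f"attempt {k}: remission + response probability exceeds 1 "
                f"({p_rem:.4f} + {p_res:.4f})"
            )
        fail = 1.0 - p_rem - p_res
        m[i, idx["death"]] = d
        m[i, idx["remission_maintenance"]] = alive * p_rem
        m[i, idx["response_maintenance"]] = alive * p_res
        nxt = idx[f"in_treatment_{k + 1}"] if k < k_max else idx["ect"]
        m[i, nxt] = alive * fail
    r = probs.relapse_annual
    for s in ("response_maintenance", "remission_maintenance"):
        i = idx[s]
        m[i, idx["death"]] = d
        m[i, idx["relapse"]] = alive * r
        m[i, i] = alive * (1.0 - r)
    i = idx["relapse"]
    m[i, idx["death"]] = d
    m[i, idx[f"in_treatment_{reentry_attempt}"]] = alive
    i = idx["ect"]
    e = probs.ect_remission
    m[i, idx["death"]] = d
    m[i, idx["remission_maintenance"]] = alive * e
    m[i, i] = alive * (1.0 - e)
    m[idx["death"], idx["death"]] = 1.0
    return m


def build_strategy_model(spec: StrategySpec, ps: ParameterSet) -> tuple[TransitionModel, RewardModel]:
    """Assemble the transition and reward structure for one arm."""
    space = build_state_space(spec)
    probs = ClinicalProbabilities.from_parameter_set(ps, spec.label)
    matrix = build_transition_matrix(spec, probs,
                                     reentry_attempt=ps.options.relapse_reentry_attempt)
    tm = TransitionModel.homogeneous_from(space, matrix)
    costs = CostInputs.from_parameter_set(ps)
    utils = UtilityInputs.from_parameter_set(ps)
    cost_vec = [annual_treatment_cost(spec, s, costs) for s in space.states]
    util_vec = [state_utility(s, utils) for s in space.states]
    rm = RewardModel.from_vectors(space, cost_vec, util_vec)
    return tm, rm


def lifetime_horizon(le: LifeExpectancy, mode: str = "likely") -> int:
    """Number of annual cycles for a cohort under the chosen longevity mode."""
    try:
        return int({"likely": le.likely, "low": le.low, "high": le.high}[mode])
    except KeyError:
        raise ValueError(f"horizon mode must be likely/low/high, got {mode!r}") from None


def strategy_model_to_dict(spec: StrategySpec, ps: ParameterSet) -> dict:
    """JSON-serializable audit description of one arm's model."""
    tm, rm = build_strategy_model(spec, ps)
    space = tm.state_space
    c, u = rm.reward_matrices(1)
    return {
        "strategy": spec.label,
        "max_attempts": spec.max_attempts,
        "states": list(space.states),
        "absorbing": sorted(space.absorbing),
        "transition_matrix": tm.transition(0).tolist(),
        "annual_cost_usd": c[0].tolist(),
        "annual_utility": u[0].tolist(),
    }


# ---------------------------------------------------------------------------
# convenience pipeline


def run_strategy(ps: ParameterSet, label: str, horizon_mode: str = "likely",
                 max_attempts: int = 4) -> StrategyOutcome:
    """Build one arm, run the cohort over the lifetime horizon, discount."""
    spec = StrategySpec(label=label, max_attempts=max_attempts)
    tm, rm = build_strategy_model(spec, ps)
    horizon = lifetime_horizon(ps.life_expectancy, horizon_mode)
    initial = np.zeros(len(tm.state_space))
    initial[tm.state_space.index("in_treatment_1")] = 1.0
    trace = run_cohort(tm, initial, horizon)
    out = discounted_totals(trace, rm, ps.discount_rate,
                            half_cycle_correction=ps.options.half_cycle_correction,
                            label=label)
    return out


def compare_strategies(ps: ParameterSet, horizon_mode: str = "likely",
                       wtp: float | None = None) -> ComparisonResult:
    """Run both arms and compare rTMS (focal) against pharmacotherapy."""
    a = run_strategy(ps, RTMS, horizon_mode)
    b = run_strategy(ps, PHARMA, horizon_mode)
    return icer(a, b, wtp=ps.wtp if wtp is None else wtp, rounding=False)
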