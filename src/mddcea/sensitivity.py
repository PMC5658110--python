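"""One-way sensitivity analysis, tornado diagrams, and probabilistic
sensitivity analysis over the full two-arm pipeline.

All analyses perturb a validated base-case :class:`ParameterSet` and re-run
both strategy arms end to end.  The decision objective is the net monetary
benefit difference (rTMS minus pharmacotherapy) at the scenario's
willingness-to-pay; at WTP = 0 this reduces to the negative incremental
cost, so a one-way "threshold" is the parameter value at which rTMS stops
(or starts) being the less costly alternative.

The PSA is second-order: it samples parameter values from their declared
distributions (not individual patient paths) and re-evaluates the cohort
model per draw, summarizing the (dQALY, dCost) cloud by cost-effectiveness
plane quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .economics import nmb, quadrant_of
from .params_io import Parameter, ParameterSet, realize
from .treatment_model import PHARMA, RTMS, run_strategy

QUADRANTS = ("NE", "SE", "SW", "NW")


@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    grid: tuple[tuple[float, float, float], ...]  # (value, NMB_rTMS, NMB_pharma)
    thresholds: tuple[float, ...]
    direction: str  # which side of the first threshold prefers rTMS
    monotone: bool

    @property
    def threshold(self) -> Optional[float]:
        """First crossing of the NMB difference, if any."""
        return self.thresholds[0] if self.thresholds else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, columns=["value", "nmb_rtms_usd", "nmb_pharma_usd"])


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    nmb_at_low: float
    nmb_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


@dataclass(frozen=True)
class PsaResult:
    draws: np.ndarray  # (n, 2) columns: delta_qaly, delta_cost
    n: int
    seed: int
    quadrant_fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=["delta_qaly", "delta_cost_usd"])
        df.insert(0, "draw", np.arange(self.n))
        df["quadrant"] = [quadrant_of(q, c) for q, c in self.draws]
        return df


# ---------------------------------------------------------------------------
# objective helpers


def nmb_difference(ps: ParameterSet, wtp: Optional[float] = None,
                   horizon_mode: str = "likely") -> float:
    """NMB(rTMS) - NMB(pharmacotherapy) for a point parameter set."""
    w = ps.wtp if wtp is None else wtp
    a = run_strategy(ps, RTMS, horizon_mode)
    b = run_strategy(ps, PHARMA, horizon_mode)
    return nmb(a, w) - nmb(b, w)


def _nmb_pair(ps: ParameterSet, wtp: float, horizon_mode: str) -> tuple[float, float]:
    a = run_strategy(ps, RTMS, horizon_mode)
    b = run_strategy(ps, PHARMA, horizon_mode)
    return nmb(a, wtp), nmb(b, wtp)


# ---------------------------------------------------------------------------
# one-way threshold analysis


def one_way_threshold(ps: ParameterSet, parameter: str,
                      wtp: Optional[float] = None,
                      tolerance: float = 1e-6,
                      grid_points: int = 21,
                      horizon_mode: str = "likely") -> OneWayResult:
    """Locate where the preferred strategy flips as one parameter varies.

    The NMB difference is evaluated on >= 21 evenly spaced points over the
    parameter's [low, high] range (returned for plotting); each sign change
    is refined by bisection to ``tolerance``.  Multiple sign changes are all
    reported and the result flagged non-monotone.
    """
    p = ps.parameters[parameter]
    if not p.low < p.high:
        raise ValueError(f"parameter {parameter!r} needs low < high for one-way analysis")
    w = ps.wtp if wtp is None else wtp
    grid_points = max(int(grid_points), 21)
    values = np.linspace(p.low, p.high, grid_points)

    def f(v: float) -> float:
        return nmb_difference(realize(ps, {parameter: float(v)}), wtp=w,
                              horizon_mode=horizon_mode)

    pairs = [_nmb_pair(realize(ps, {parameter: float(v)}), w, horizon_mode)
             for v in values]
    grid = tuple((float(v), a, b) for v, (a, b) in zip(values, pairs))
    diffs = np.array([a - b for a, b in pairs])

    roots: list[float] = []
    signs = np.sign(diffs)
    for i in range(len(values) - 1):
        if signs[i] == 0.0:
            roots.append(float(values[i]))
        elif signs[i] * signs[i + 1] < 0:
            r = optimize.bisect(f, values[i], values[i + 1], xtol=tolerance)
            roots.append(float(r))
    if signs[-1] == 0.0:
        roots.append(float(values[-1]))

    if diffs[0] > 0:
        direction = "rTMS preferred below threshold" if roots else "rTMS preferred throughout"
    elif diffs[0] < 0:
        direction = "rTMS preferred above threshold" if roots else "pharmacotherapy preferred throughout"
    else:
        direction = "indifferent at range low"
    return OneWayResult(parameter=parameter, grid=grid, thresholds=tuple(roots),
                        direction=direction, monotone=len(roots) <= 1)


# ---------------------------------------------------------------------------
# tornado


def tornado(ps: ParameterSet, parameters: Sequence[str],
            wtp: Optional[float] = None,
            horizon_mode: str = "likely",
            objective: str = "incremental") -> list[TornadoEntry]:
    """One-way NMB swings at each parameter's range ends, ranked by spread.

    ``objective='incremental'`` (default) scores NMB(rTMS) - NMB(pharma),
    the quantity that decides between the arms, so costs common to both
    arms cancel; ``objective='focal'`` scores NMB of the rTMS arm alone.
    Ties in spread break alphabetically so ranking is order-independent.
    """
    if not parameters:
        raise ValueError("tornado requires at least one parameter")
    if objective not in ("incremental", "focal"):
        raise ValueError("objective must be 'incremental' or 'focal'")
    w = ps.wtp if wtp is None else wtp

    def score(point: ParameterSet) -> float:
        a, b = _nmb_pair(point, w, horizon_mode)
        return a - b if objective == "incremental" else a

    entries = []
    for name in parameters:
        p = ps.parameters[name]
        entries.append(TornadoEntry(
            parameter=name,
            nmb_at_low=score(realize(ps, {name: p.low})),
            nmb_at_high=score(realize(ps, {name: p.high})),
        ))
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def tornado_frame(entries: Iterable[TornadoEntry], ps: ParameterSet) -> pd.DataFrame:
    rows = []
    for e in entries:
        p = ps.parameters[e.parameter]
        rows.append({
            "parameter": e.parameter, "low": p.low, "high": p.high,
            "nmb_at_low_usd": e.nmb_at_low, "nmb_at_high_usd": e.nmb_at_high,
            "spread_usd": e.spread,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


_MAX_REJECTIONS = 1000


def sample_parameter(p: Parameter, rng: np.random.Generator) -> float:
    """Draw one value from a parameter's distribution, within role bounds.

    Draws outside the role bounds (possible only for truncated-normal specs
    with loose explicit bounds, or degenerate inputs) are rejected and
    resampled, erroring after 1000 rejections.
    """
    if p.distribution is None:
        raise ValueError(f"parameter {p.name!r} has no distribution")
    fam, pars = p.distribution.family, p.distribution.parameters
    lo, hi = p.role_bounds()
    for _ in range(_MAX_REJECTIONS):
        if fam == "point":
            v = pars[0]
        elif fam == "uniform":
            v = rng.uniform(pars[0], pars[1])
        elif fam == "beta":
            v = rng.beta(pars[0], pars[1])
        elif fam == "gamma":
            v = rng.gamma(shape=pars[0], scale=pars[1])
        elif fam == "truncated-normal":
            mu, sigma, a, b = pars
            if sigma == 0:
                v = mu
            else:
                v = stats.truncnorm.rvs((a - mu) / sigma, (b - mu) / sigma,
                                        loc=mu, scale=sigma, random_state=rng)
        else:  # pragma: no cover - DistributionSpec validates the family
            raise ValueError(f"unknown family {fam!r}")
        if lo <= v <= hi:
            return float(v)
        if fam == "point":
            break
    raise ValueError(f"sampling {p.name!r} failed to satisfy {p.role} bounds "
                     f"after {_MAX_REJECTIONS} rejections")


def run_psa(ps: ParameterSet, n: int = 1000, seed: int = 0,
            wtp: Optional[float] = None,
            horizon_mode: str = "likely") -> PsaResult:
    """Monte Carlo parameter-uncertainty analysis of the two-arm comparison.

    Each of the ``n`` iterations draws every distributed parameter from its
    DistributionSpec (one independent RNG substream per draw index, so the
    result is reproducible and order-independent), re-runs both arms, and
    records the incremental (dQALY, dCost) point, rTMS minus
    pharmacotherapy.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    varied = [p for p in ps.parameters.values() if p.distribution is not None]
    if not varied:
        raise ValueError("PSA requires at least one parameter with a distribution")
    streams = np.random.SeedSequence(seed).spawn(n)
    draws = np.empty((n, 2))
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        draw = {p.name: sample_parameter(p, rng) for p in varied}
        # joint invariants are enforced by rejection at the draw level
        for _ in range(_MAX_REJECTIONS):
            if _draw_consistent(ps, draw):
                break
            draw = {p.name: sample_parameter(p, rng) for p in varied}
        else:
            raise ValueError("could not draw a jointly consistent parameter set")
        point = realize(ps, draw)
        a = run_strategy(point, RTMS, horizon_mode)
        b = run_strategy(point, PHARMA, horizon_mode)
        draws[i] = (a.qaly - b.qaly, a.cost - b.cost)
    fractions = quadrant_fractions([tuple(row) for row in draws])
    return PsaResult(draws=draws, n=n, seed=seed, quadrant_fractions=fractions)


def _draw_consistent(ps: ParameterSet, draw: dict[str, float]) -> bool:
    """Joint feasibility of a draw (per-arm remission + response <= 1)."""
    def val(name: str) -> float:
        return draw.get(name, ps.value(name))

    for arm in ("rtms", "pharma"):
        if val(f"p_remission_{arm}") + val(f"p_response_{arm}") > 1.0:
            return False
    return True


def quadrant_fractions(points: Sequence[tuple[float, float]]) -> dict[str, float]:
    """Fraction of (dQALY, dCost) points per CE-plane quadrant.

    Uses the same closed-toward-NE boundary convention as the CE-plane
    labelling, so the four fractions always sum to 1.
    """
    if len(points) == 0:
        raise ValueError("quadrant_fractions requires a non-empty point list")
    counts = dict.fromkeys(QUADRANTS, 0)
    for dq, dc in points:
        counts[quadrant_of(dq, dc)] += 1
    total = len(points)
    return {q: counts[q] / total for q in QUADRANTS}
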