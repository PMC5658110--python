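"""Comparative health-economic outputs: NMB, ICER, dominance, CE plane.

Two strategies are compared by their discounted lifetime cost (USD) and
QALYs.  Increments are taken as focal minus comparator (here rTMS minus
pharmacotherapy).  A strategy dominates when it costs strictly less AND
yields strictly more QALYs; only genuine trade-offs (both increments of the
same sign, nonzero) carry an ICER = dC/dQ.  Net monetary benefit is
NMB = QALY * WTP - cost; at willingness-to-pay 0 every NMB is simply the
negative lifetime cost, so the least costly strategy has the highest NMB.

Reporting convention: incremental cost rounds to whole dollars, incremental
QALYs to 2 decimals, and the ICER to the nearest dollar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted lifetime cost (USD) and QALYs for one strategy."""

    label: str
    cost: float
    qaly: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.qaly < 0:
            raise ValueError("lifetime cost and QALYs must be non-negative")


@dataclass(frozen=True)
class CePlanePoint:
    """A point on the cost-effectiveness plane (x = dQALY, y = dCost)."""

    delta_qaly: float
    delta_cost: float
    quadrant: str  # NE, SE, SW, NW, or 'origin'


@dataclass(frozen=True)
class ComparisonResult:
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]  # None when dominance/equivalence makes it undefined
    dominance: str  # 'a-dominant' | 'b-dominant' | 'trade-off' | 'equivalent'
    nmb_by_strategy: dict[str, float]
    wtp: float
    labels: tuple[str, str] = ("a", "b")

    def to_dict(self) -> dict:
        return {
            "strategy_a": self.labels[0],
            "strategy_b": self.labels[1],
            "delta_cost_usd": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer_usd_per_qaly": self.icer,
            "dominance": self.dominance,
            "wtp_usd_per_qaly": self.wtp,
            "nmb_usd": dict(self.nmb_by_strategy),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit: QALYs x willingness-to-pay, less cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return outcome.qaly * wtp - outcome.cost


def classify_dominance(a: StrategyOutcome, b: StrategyOutcome) -> str:
    """Strict-inequality dominance label for a versus b.

    Ties on either axis are never dominance: identical outcomes are
    'equivalent', anything else without strict double inequality is a
    'trade-off'.
    """
    if a.cost == b.cost and a.qaly == b.qaly:
        return "equivalent"
    if a.cost < b.cost and a.qaly > b.qaly:
        return "a-dominant"
    if b.cost < a.cost and b.qaly > a.qaly:
        return "b-dominant"
    return "trade-off"


def icer(a: StrategyOutcome, b: StrategyOutcome, wtp: float = 0.0,
         rounding: bool = True) -> ComparisonResult:
    """Incremental comparison of a (focal) versus b (comparator).

    delta_cost = a.cost - b.cost, delta_qaly = a.qaly - b.qaly.  The ICER is
    reported only for trade-offs with nonzero dQALY; under dominance or
    equivalence it is undefined (None).  A trade-off with dC = 0 reports
    ICER 0; one with dQ = 0 reports +/-infinity (the conventional "no
    benefit" limit).

    With ``rounding`` (the default) increments and the ratio follow the
    reporting convention (whole dollars, 2-decimal QALYs).
    """
    dc = a.cost - b.cost
    dq = a.qaly - b.qaly
    if rounding:
        dc = float(round(dc))
        dq = round(dq, 2)
    dominance = classify_dominance(a, b)
    ratio: Optional[float]
    if dominance in ("a-dominant", "b-dominant", "equivalent"):
        ratio = None
    elif dq == 0:
        ratio = math.inf if dc > 0 else (-math.inf if dc < 0 else None)
    elif dc == 0:
        ratio = 0.0
    else:
        ratio = dc / dq
        if rounding:
            ratio = float(round(ratio))
    return ComparisonResult(
        delta_cost=dc,
        delta_qaly=dq,
        icer=ratio,
        dominance=dominance,
        nmb_by_strategy={a.label or "a": nmb(a, wtp), b.label or "b": nmb(b, wtp)},
        wtp=wtp,
        labels=(a.label or "a", b.label or "b"),
    )


def ce_plane_point(a: StrategyOutcome, b: StrategyOutcome) -> CePlanePoint:
    """(dQALY, dCost) of a versus b with its cost-effectiveness quadrant.

    SE (dQ > 0, dC < 0) is the dominant quadrant for the focal strategy; NW
    is dominated.  Points on an axis are assigned to the closed-east /
    closed-north side (dQ = 0 counts as east, dC = 0 as north) so quadrant
    tallies over a scatter always partition; the exact origin is labelled
    'origin'.
    """
    dq = a.qaly - b.qaly
    dc = a.cost - b.cost
    if dq == 0 and dc == 0:
        return CePlanePoint(0.0, 0.0, "origin")
    return CePlanePoint(dq, dc, quadrant_of(dq, dc))


def quadrant_of(delta_qaly: float, delta_cost: float) -> str:
    """Quadrant of a CE-plane point; boundaries closed toward NE."""
    east = delta_qaly >= 0
    north = delta_cost >= 0
    if east and north:
        return "NE"
    if east and not north:
        return "SE"
    if not east and not north:
        return "SW"
    return "NW"
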