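"""Strategy comparison: ICERs, dominance frontier, net monetary benefit.

Given discounted totals per strategy (cost, life-years, QALYs), this module
computes incremental cost-effectiveness ratios along the efficient frontier,
classifies strategies as dominated / extendedly dominated / on the frontier,
and evaluates net monetary benefit at a willingness-to-pay threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StrategyOutcome",
    "ICERResult",
    "ComparisonResult",
    "icer",
    "dominance_frontier",
    "net_monetary_benefit",
]

#: QALY difference below which two strategies count as equally effective.
EFFECT_TOLERANCE = 1e-9

ON_FRONTIER = "on frontier"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly dominated"


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one strategy (per patient)."""

    name: str
    cost: float
    ly: float
    qaly: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be non-negative")
        if self.qaly > self.ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years (utilities <= 1)")


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of strategy ``a`` against comparator ``b``.

    ``label`` is "icer" for a well-defined positive trade-off, "dominant"
    when ``a`` is cheaper and more effective, "dominated" when ``a`` is more
    costly and less effective, and "undefined" when the QALY difference is
    below the effect tolerance.
    """

    d_cost: float
    d_qaly: float
    d_ly: float
    per_qaly: float | None
    per_ly: float | None
    label: str


def icer(a: StrategyOutcome, b: StrategyOutcome) -> ICERResult:
    """ICER of strategy ``a`` versus comparator ``b``: dCost / dQALY."""
    d_cost = a.cost - b.cost
    d_qaly = a.qaly - b.qaly
    d_ly = a.ly - b.ly
    if abs(d_qaly) <= EFFECT_TOLERANCE:
        return ICERResult(d_cost, d_qaly, d_ly, None, None, "undefined")
    if d_cost < 0 and d_qaly > 0:
        label = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        label = "dominated"
    else:
        label = "icer"
    per_ly = d_cost / d_ly if abs(d_ly) > EFFECT_TOLERANCE else None
    return ICERResult(d_cost, d_qaly, d_ly, d_cost / d_qaly, per_ly, label)


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """NMB = wtp * QALYs - cost at willingness-to-pay ``wtp`` ($/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * outcome.qaly - outcome.cost


@dataclass
class ComparisonResult:
    """Dominance classification and frontier ICERs for a set of strategies."""

    outcomes: list[StrategyOutcome]
    frontier: list[str]
    labels: dict[str, str]
    increments: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the usual base-case layout: one row per strategy,
        ICER columns filled along the frontier and dominance labels elsewhere."""
        rows = []
        icers = {inc["strategy"]: inc for inc in self.increments}
        for o in sorted(self.outcomes, key=lambda o: (o.cost, o.qaly, o.name)):
            label = self.labels[o.name]
            if label != ON_FRONTIER:
                per_ly = per_qaly = label
            elif o.name in icers:
                inc = icers[o.name]
                per_ly = "" if inc["icer_per_ly"] is None else f"{inc['icer_per_ly']:.0f}"
                per_qaly = "" if inc["icer_per_qaly"] is None else f"{inc['icer_per_qaly']:.0f}"
            else:
                per_ly = per_qaly = "-"
            rows.append(
                {
                    "strategy": o.name,
                    "total_cost": o.cost,
                    "ly": o.ly,
                    "qaly": o.qaly,
                    "icer_per_ly": per_ly,
                    "icer_per_qaly": per_qaly,
                }
            )
        return pd.DataFrame(rows)


def _strictly_dominated(o: StrategyOutcome, others: list[StrategyOutcome]) -> bool:
    for p in others:
        if p is o:
            continue
        if p.cost <= o.cost + 1e-12 and p.qaly >= o.qaly - EFFECT_TOLERANCE:
            if p.cost < o.cost - 1e-12 or p.qaly > o.qaly + EFFECT_TOLERANCE:
                return True
    return False


def dominance_frontier(outcomes: list[StrategyOutcome]) -> ComparisonResult:
    """Classify strategies and compute pairwise ICERs along the frontier.

    Strategies are sorted by cost (name as tie-break); strictly dominated
    ones (more costly, no more effective) are removed first, then extendedly
    dominated ones (sequential ICER not lower than the next segment's) until
    frontier ICERs strictly increase.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies to compare")
    ordered = sorted(outcomes, key=lambda o: (o.cost, o.qaly, o.name))
    labels = {o.name: ON_FRONTIER for o in ordered}

    candidates = []
    for o in ordered:
        if _strictly_dominated(o, ordered):
            labels[o.name] = DOMINATED
        else:
            candidates.append(o)

    # extended dominance: drop interior strategies whose segment ICER is not
    # below the ICER of the following segment
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_in = icer(mid, lo)
            icer_out = icer(hi, mid)
            if icer_in.per_qaly is None or icer_out.per_qaly is None:
                continue
            if icer_in.per_qaly >= icer_out.per_qaly:
                labels[mid.name] = EXT_DOMINATED
                del candidates[i]
                changed = True
                break

    increments = []
    for prev, cur in zip(candidates[:-1], candidates[1:]):
        inc = icer(cur, prev)
        increments.append(
            {
                "strategy": cur.name,
                "comparator": prev.name,
                "d_cost": inc.d_cost,
                "d_qaly": inc.d_qaly,
                "d_ly": inc.d_ly,
                "icer_per_qaly": inc.per_qaly,
                "icer_per_ly": inc.per_ly,
                "label": inc.label,
            }
        )
    return ComparisonResult(
        outcomes=list(outcomes),
        frontier=[o.name for o in candidates],
        labels=labels,
        increments=increments,
    )
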