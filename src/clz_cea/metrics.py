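"""Comparative cost-effectiveness metrics.

ICER with quadrant-aware dominance classification, net monetary benefit,
and the cost-effectiveness frontier with extended-dominance detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import pandas as pd

from .config import Strategy, round_gbp
from .engine import CEAOutcome

#: Dominance statuses a pairwise comparison can carry.
STATUS_ICER = "icer"            # more effective and more costly: ratio meaningful
STATUS_DOMINANT = "dominant"    # comparator cheaper and at least as effective
STATUS_DOMINATED = "dominated"  # comparator costlier and at most as effective
STATUS_SOUTHWEST = "southwest"  # cheaper but less effective: ratio reported with flag
STATUS_EQUIVALENT = "equivalent"


@dataclass
class ComparisonResult:
    """Incremental comparison of ``comparator`` against ``reference``.

    ``icer`` is defined only when delta_qalys != 0; for dominance quadrants
    no ratio is computed (mirroring the convention that no ICER is reported
    against a dominating option).
    """

    comparator: Strategy
    reference: Strategy
    delta_cost: float
    delta_qalys: float
    status: str
    icer: Optional[float] = None
    wtp: Optional[float] = None
    within_threshold: Optional[bool] = None
    outcome_comparator: Optional[CEAOutcome] = None
    outcome_reference: Optional[CEAOutcome] = None

    def to_dict(self) -> dict:
        d = {
            "comparator": self.comparator.label,
            "reference": self.reference.label,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "status": self.status,
            "icer": self.icer,
            "wtp": self.wtp,
            "within_threshold": self.within_threshold,
        }
        if self.outcome_comparator is not None:
            d["outcome_comparator"] = self.outcome_comparator.to_dict()
        if self.outcome_reference is not None:
            d["outcome_reference"] = self.outcome_reference.to_dict()
        return d

    def to_rows(self) -> List[dict]:
        rows = []
        for outcome, is_ref in (
            (self.outcome_reference, True),
            (self.outcome_comparator, False),
        ):
            if outcome is None:
                continue
            rows.append(
                {
                    "strategy": outcome.strategy.label,
                    "cost": round_gbp(outcome.discounted_cost),
                    "qalys": outcome.discounted_qalys,
                    "delta_cost": None if is_ref else self.delta_cost,
                    "delta_qalys": None if is_ref else self.delta_qalys,
                    "icer": None if is_ref else self.icer,
                    "status": None if is_ref else self.status,
                }
            )
        return rows


def icer(
    outcome_new: CEAOutcome,
    outcome_ref: CEAOutcome,
    wtp: Optional[float] = None,
) -> ComparisonResult:
    """Classify the incremental comparison and compute the ICER when defined.

    delta = new - reference.  Quadrants: both deltas positive -> ICER;
    cheaper-and-at-least-as-effective -> dominant; costlier-and-at-most-as-
    effective -> dominated; cheaper-but-less-effective -> south-west ratio
    with explicit flag (a bare ratio there inverts the decision logic).
    """
    dc = outcome_new.discounted_cost - outcome_ref.discounted_cost
    dq = outcome_new.discounted_qalys - outcome_ref.discounted_qalys

    if dc == 0.0 and dq == 0.0:
        status, ratio = STATUS_EQUIVALENT, None
    elif dc <= 0.0 and dq >= 0.0:
        status, ratio = STATUS_DOMINANT, None
    elif dc >= 0.0 and dq <= 0.0:
        status, ratio = STATUS_DOMINATED, None
    elif dq > 0.0:
        status, ratio = STATUS_ICER, dc / dq
    else:  # dq < 0 and dc < 0
        status, ratio = STATUS_SOUTHWEST, dc / dq

    within = None
    if wtp is not None:
        if wtp < 0:
            raise ValueError("willingness-to-pay must be non-negative")
        within = (wtp * dq - dc) > 0.0

    return ComparisonResult(
        comparator=outcome_new.strategy,
        reference=outcome_ref.strategy,
        delta_cost=dc,
        delta_qalys=dq,
        status=status,
        icer=ratio,
        wtp=wtp,
        within_threshold=within,
        outcome_comparator=outcome_new,
        outcome_reference=outcome_ref,
    )


def net_monetary_benefit(outcome: CEAOutcome, wtp: float) -> float:
    """NMB = wtp x QALYs - cost (both discounted)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * outcome.discounted_qalys - outcome.discounted_cost


# ---------------------------------------------------------------------------
# frontier

FRONTIER = "frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass
class FrontierEntry:
    strategy: Strategy
    cost: float
    qalys: float
    status: str
    sequential_icer: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.label,
            "cost": self.cost,
            "qalys": self.qalys,
            "dominance_status": self.status,
            "sequential_icer": self.sequential_icer,
        }


def dominance_frontier(outcomes: Sequence[CEAOutcome]) -> List[FrontierEntry]:
    """Efficient frontier over strategies: strict dominance, extended
    dominance, and sequential ICERs along the non-dominated set.

    Entries are returned sorted by QALYs ascending.  A strategy is strictly
    dominated if another is at least as effective and at most as costly
    (strict in one); extended dominated if its sequential ICER exceeds that
    of the next more-effective frontier option.
    """
    outcomes = list(outcomes)
    if len(outcomes) < 2:
        raise ValueError("dominance_frontier requires at least two outcomes")
    labels = [o.strategy.label for o in outcomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategies supplied to dominance_frontier")

    entries = [
        FrontierEntry(o.strategy, o.discounted_cost, o.discounted_qalys, FRONTIER)
        for o in outcomes
    ]
    # strict dominance
    for e in entries:
        for other in entries:
            if other is e:
                continue
            if (
                other.cost <= e.cost
                and other.qalys >= e.qalys
                and (other.cost < e.cost or other.qalys > e.qalys)
            ):
                e.status = DOMINATED
                break

    # extended dominance on the remaining set: sequential ICERs must increase
    candidates = sorted(
        [e for e in entries if e.status != DOMINATED], key=lambda e: (e.qalys, e.cost)
    )
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            prev, cur, nxt = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_in = _seq_icer(prev, cur)
            icer_out = _seq_icer(cur, nxt)
            if icer_in is not None and icer_out is not None and icer_in >= icer_out:
                cur.status = EXTENDED_DOMINATED
                candidates.pop(i)
                changed = True
                break

    for i, e in enumerate(candidates):
        e.sequential_icer = None if i == 0 else _seq_icer(candidates[i - 1], e)

    return sorted(entries, key=lambda e: (e.qalys, e.cost))


def _seq_icer(lower: FrontierEntry, upper: FrontierEntry) -> Optional[float]:
    dq = upper.qalys - lower.qalys
    if dq == 0.0:
        return None
    return (upper.cost - lower.cost) / dq


def frontier_table(entries: Sequence[FrontierEntry]) -> pd.DataFrame:
    """Frontier CSV shape: strategy, cost, qalys, dominance_status, sequential_icer."""
    return pd.DataFrame([e.to_dict() for e in entries])
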