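"""Deterministic sensitivity analyses.

One-way (tornado) analysis over named parameters, bisection threshold
search on a single parameter against a willingness-to-pay, and the
time-horizon sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._slots import SLOTS, get_slot, with_slot
from .config import ParameterSet, Strategy
from .engine import run_cohort
from .metrics import ComparisonResult, icer

#: The default one-way parameter set: the six parameters conventionally
#: varied for this model.  Prevention-rate range 20-80% is the documented
#: default; the remaining ranges are package defaults (+-25% for costs and
#: the PPV, 0-5% for the discount rate) that callers override with the
#: ranges of their own parameter table.
DEFAULT_TORNADO_PARAMETERS = (
    "prevention_rate",
    "ppv",
    "ciag_treatment_cost",
    "clz_daily_cost",
    "substitute_daily_cost",
    "discount_rate",
)


def default_tornado_ranges(params: ParameterSet) -> Dict[str, Tuple[float, float]]:
    ranges: Dict[str, Tuple[float, float]] = {"prevention_rate": (0.2, 0.8)}
    for name in ("ciag_treatment_cost", "clz_daily_cost", "substitute_daily_cost"):
        base = get_slot(params, name)
        ranges[name] = (0.75 * base, 1.25 * base)
    base_ppv = get_slot(params, "ppv")
    ranges["ppv"] = (0.75 * base_ppv, min(1.0, 1.25 * base_ppv))
    ranges["discount_rate"] = (0.0, 0.05)
    return ranges


def _signed_icer(pair: Tuple[Strategy, Strategy], params: ParameterSet) -> Tuple[float, ComparisonResult]:
    """ICER as the raw ratio dC/dQ (nan when dQ = 0), plus the full comparison.

    The raw ratio is what a tornado axis plots; the comparison result carries
    the quadrant classification for readers of the table.
    """
    new, ref = pair
    _, out_new = run_cohort(new, params)
    _, out_ref = run_cohort(ref, params)
    comp = icer(out_new, out_ref)
    if comp.delta_qalys == 0.0:
        return math.nan, comp
    return comp.delta_cost / comp.delta_qalys, comp


@dataclass
class TornadoRecord:
    name: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    status_low: str
    status_high: str

    @property
    def swing(self) -> float:
        if math.isnan(self.icer_low) or math.isnan(self.icer_high):
            return 0.0
        return abs(self.icer_high - self.icer_low)


@dataclass
class TornadoResult:
    base_icer: float
    records: List[TornadoRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "parameter": r.name,
                    "low": r.low,
                    "high": r.high,
                    "icer_low": r.icer_low,
                    "icer_high": r.icer_high,
                    "swing": r.swing,
                    "base_icer": self.base_icer,
                }
                for r in self.records
            ]
        )
        return df


def one_way_tornado(
    params: ParameterSet,
    pair: Tuple[Strategy, Strategy],
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> TornadoResult:
    """Vary each named parameter to its low/high bound (all else at base),
    recompute both arms and the ICER, and rank records by swing width.

    Ties in swing break by parameter name (stable alphabetical order).
    """
    if ranges is None:
        ranges = default_tornado_ranges(params)
    for name, (lo, hi) in ranges.items():
        if name not in SLOTS:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: {', '.join(sorted(SLOTS))}"
            )
        if lo > hi:
            raise ValueError(f"range for {name} has low > high: ({lo}, {hi})")

    base_icer, _ = _signed_icer(pair, params)
    records = []
    for name in sorted(ranges):
        lo, hi = ranges[name]
        icer_lo, comp_lo = _signed_icer(pair, with_slot(params, name, lo))
        icer_hi, comp_hi = _signed_icer(pair, with_slot(params, name, hi))
        records.append(
            TornadoRecord(
                name=name,
                low=lo,
                high=hi,
                icer_low=icer_lo,
                icer_high=icer_hi,
                status_low=comp_lo.status,
                status_high=comp_hi.status,
            )
        )
    records.sort(key=lambda r: -r.swing)  # stable: equal swings keep name order
    return TornadoResult(base_icer=base_icer, records=records)


@dataclass
class ThresholdResult:
    """Result of a threshold search; ``found`` is False when the ICER-WTP
    difference does not change sign over the bracket (no exception raised)."""

    found: bool
    parameter: str
    value: Optional[float] = None
    icer_at_value: Optional[float] = None
    message: str = ""


def threshold_search(
    param_name: str,
    wtp: float,
    bracket: Tuple[float, float],
    params: ParameterSet,
    pair: Tuple[Strategy, Strategy],
    icer_tol: float = 1.0,
    x_tol: float = 1e-6,
) -> ThresholdResult:
    """Bisection for the parameter value at which the ICER crosses ``wtp``.

    Stops when |ICER - wtp| <= ``icer_tol`` (default GBP 1/QALY) or the
    bracket width falls below ``x_tol``.
    """
    lo, hi = bracket
    if lo > hi:
        raise ValueError(f"bracket has low > high: {bracket}")

    def f(x: float) -> float:
        value, _ = _signed_icer(pair, with_slot(params, param_name, x))
        return value - wtp

    f_lo, f_hi = f(lo), f(hi)
    if math.isnan(f_lo) or math.isnan(f_hi) or f_lo * f_hi > 0:
        return ThresholdResult(
            found=False, parameter=param_name, message="no crossing in bracket"
        )
    while hi - lo > x_tol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) <= icer_tol:
            return ThresholdResult(
                found=True, parameter=param_name, value=mid, icer_at_value=f_mid + wtp
            )
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    mid = 0.5 * (lo + hi)
    return ThresholdResult(
        found=True, parameter=param_name, value=mid, icer_at_value=f(mid) + wtp
    )


@dataclass
class HorizonSweepResult:
    table: pd.DataFrame  # columns: years, icer, status
    first_below_threshold: Optional[int]
    wtp: float


def horizon_sweep(
    years: Sequence[int],
    params: ParameterSet,
    pair: Tuple[Strategy, Strategy],
) -> HorizonSweepResult:
    """Re-run the full model at each horizon and report the ICER series.

    Onset curves shorter than the horizon are extended with their last
    value (onset is concentrated in the first months, so the tail is
    near-flat anyway).  ``first_below_threshold`` is the smallest horizon
    whose comparison is acceptable at the country threshold (ICER below it,
    or the comparator dominant).
    """
    wtp = params.country.wtp_threshold
    rows = []
    first_below: Optional[int] = None
    for y in sorted(years):
        if y < 1:
            raise ValueError("each horizon must be at least 1 year")
        p = params.model_copy(deep=True)
        p.horizon_years = float(y)
        value, comp = _signed_icer(pair, p)
        rows.append({"years": y, "icer": value, "status": comp.status})
        acceptable = comp.status == "dominant" or (
            comp.status == "icer" and value < wtp
        )
        if acceptable and first_below is None:
            first_below = y
    return HorizonSweepResult(
        table=pd.DataFrame(rows), first_below_threshold=first_below, wtp=wtp
    )
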