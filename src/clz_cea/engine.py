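"""Two-state, time-inhomogeneous monthly Markov cohort engine.

The cohort starts fully in "OnClozapine".  Each cycle, a fraction of those
still on clozapine develops CIAG and switches permanently to a substitute
antipsychotic ("OnSubstitute" is absorbing; re-challenge is prohibited).
There is no death or sepsis state and no WBC-based exit: CIAG-related
mortality under registry monitoring is negligible and WBC-triggered
discontinuation is not modelled.

Cost flows per cycle: state-specific daily drug cost x cycle length, the
blood-monitoring schedule (weekly for the first ``weekly_monitoring_weeks``
weeks, biweekly thereafter; clozapine arm only), a one-time CIAG treatment
cost charged in the transition cycle, and a one-time HLA typing cost at
cycle 0 for guided strategies.  QALYs accrue as state utility x cycle length
in years.  Cycle-t rewards belong to the state occupied at the cycle start
(transitions take effect at the cycle boundary); all cycle-t flows are
discounted by (1+rate)^(-t/12 months).

Because the transition structure is a pure one-way flow, the occupancy of
"OnClozapine" in cycle t equals the survival product prod_{s<=t}(1-q_s),
which the engine exploits to run fully vectorised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_CYCLE_DAYS,
    ConfigError,
    CountryProfile,
    HLAParameters,
    OnsetCurve,
    ParameterSet,
    Strategy,
)

DAYS_PER_YEAR = 365.25


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and incidence for one strategy.

    ``occupancy`` has ``cycles + 1`` rows; row 0 is the starting state
    [1, 0] and row t the post-transition occupancy during cycle t.  Column 0
    is OnClozapine, column 1 OnSubstitute.
    """

    cycles: int
    occupancy: np.ndarray
    incident_ciag: np.ndarray
    discounted_cost: np.ndarray  # per-cycle, cycle 0 holds the HLA test cost
    discounted_qalys: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.cycles + 1),
                "on_clozapine": self.occupancy[:, 0],
                "on_substitute": self.occupancy[:, 1],
                "incident_ciag": np.concatenate([[0.0], self.incident_ciag]),
                "discounted_cost": self.discounted_cost,
                "discounted_qalys": self.discounted_qalys,
            }
        )


@dataclass
class CEAOutcome:
    """Discounted (and undiscounted) cost and QALYs per patient for one arm."""

    strategy: Strategy
    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    cost_breakdown: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.label,
            "discounted_cost": self.discounted_cost,
            "discounted_qalys": self.discounted_qalys,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_qalys": self.undiscounted_qalys,
            "cost_breakdown": dict(self.cost_breakdown),
        }


# ---------------------------------------------------------------------------
# building blocks

def discount_factor(
    annual_rate: float, cycle_index: int, cycle_length_days: float = DEFAULT_CYCLE_DAYS
) -> float:
    """(1 + rate)^(-t) with t in years = cycle_index x cycle_length / 365.25."""
    if annual_rate <= -1.0:
        raise ValueError(f"annual_rate must exceed -1, got {annual_rate}")
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    t_years = cycle_index * cycle_length_days / DAYS_PER_YEAR
    return (1.0 + annual_rate) ** (-t_years)


def daily_to_cycle_cost(daily_cost: float, cycle_length_days: float = DEFAULT_CYCLE_DAYS) -> float:
    if daily_cost < 0 or cycle_length_days < 0:
        raise ValueError("inputs must be non-negative")
    return daily_cost * cycle_length_days


def effective_onset_curve(
    curve: OnsetCurve,
    strategy: Strategy,
    hla: HLAParameters,
    prevention_rate: Optional[float] = None,
) -> OnsetCurve:
    """Scale the onset curve by (1 - prevention rate) for HLA-guided arms.

    Unguided strategies return the curve unchanged.  ``prevention_rate``
    overrides ``hla.prevention_rate`` (used by the PPV-derivation hook).
    """
    if not strategy.hla_guided:
        return curve
    r = hla.prevention_rate if prevention_rate is None else prevention_rate
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"prevention rate must lie in [0, 1], got {r}")
    q = np.asarray(curve.monthly_onset_prob, dtype=float) * (1.0 - r)
    return OnsetCurve(cutoff=curve.cutoff, monthly_onset_prob=q.tolist())


def monitoring_test_days(
    weekly_monitoring_weeks: int, total_days: float
) -> np.ndarray:
    """Day-resolution blood-test schedule: weekly tests at days 7, 14, ...,
    7W, then biweekly at 7W+14, 7W+28, ... up to ``total_days``."""
    weekly = 7.0 * np.arange(1, weekly_monitoring_weeks + 1)
    last = 7.0 * weekly_monitoring_weeks
    n_biweekly = max(0, int(math.floor((total_days - last) / 14.0)))
    biweekly = last + 14.0 * np.arange(1, n_biweekly + 1)
    days = np.concatenate([weekly, biweekly])
    return days[days <= total_days]


def monitoring_cost_stream(
    country: CountryProfile,
    on_clz: bool,
    n_cycles: int,
    cycle_length_days: float = DEFAULT_CYCLE_DAYS,
) -> np.ndarray:
    """Per-cycle monitoring cost for a patient on clozapine throughout.

    Cycle t covers days ((t-1)L, tL]; a test on day d is charged to cycle
    ceil(d/L).  Substitute-arm patients incur no monitoring cost.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    stream = np.zeros(n_cycles)
    if not on_clz or country.per_test_cost == 0.0:
        return stream
    days = monitoring_test_days(country.weekly_monitoring_weeks, n_cycles * cycle_length_days)
    cycle_idx = np.ceil(days / cycle_length_days).astype(int)
    cycle_idx = np.clip(cycle_idx, 1, n_cycles)
    counts = np.bincount(cycle_idx, minlength=n_cycles + 1)[1:]
    return counts * country.per_test_cost


def prevention_rate_in_effect(params: ParameterSet, cutoff: int) -> float:
    """The prevention rate the engine applies to HLA-guided arms.

    Base case: ``hla.prevention_rate`` is primitive.  With the opt-in
    ``derive_prevention_from_ppv`` flag, the rate is recomputed as
    carrier_prevention_efficacy x sensitivity implied by Bayes' theorem
    (ppv x carrier frequency / cumulative incidence at the strategy's
    cutoff), so one-way variation of the PPV propagates to the ICER.
    """
    if not params.derive_prevention_from_ppv:
        return params.hla.prevention_rate
    cum = params.curve_for(cutoff).cumulative_incidence
    if cum <= 0.0:
        return 0.0
    implied_sensitivity = params.hla.ppv * params.hla.phenotype_frequency / cum
    return float(np.clip(params.carrier_prevention_efficacy * implied_sensitivity, 0.0, 1.0))


def _horizon_cycles(params: ParameterSet) -> int:
    return int(round(params.horizon_years * 12))


def _aligned_onset_probs(curve: OnsetCurve, n_cycles: int) -> np.ndarray:
    """Truncate or extend (with the last value) the curve to n_cycles."""
    q = np.asarray(curve.monthly_onset_prob, dtype=float)
    if len(q) >= n_cycles:
        return q[:n_cycles]
    return np.concatenate([q, np.full(n_cycles - len(q), q[-1])])


# ---------------------------------------------------------------------------
# cohort run

def run_cohort(strategy: Strategy, params: ParameterSet) -> tuple[CohortTrace, CEAOutcome]:
    """Run the cohort model for one arm; returns the trace and the outcome."""
    n = _horizon_cycles(params)
    cl = params.cycle_length_days
    country = params.country

    base_curve = params.curve_for(strategy.anc_cutoff)
    r = prevention_rate_in_effect(params, strategy.anc_cutoff) if strategy.hla_guided else 0.0
    q = _aligned_onset_probs(base_curve, n) * (1.0 - r)
    if np.any(q < 0.0) or np.any(q > 1.0):
        raise ValueError("effective onset probabilities left [0, 1] after scaling")

    surv = np.cumprod(1.0 - q)                      # P(still on CLZ after cycle t)
    surv_prev = np.concatenate([[1.0], surv[:-1]])  # occupancy entering cycle t
    incident = surv_prev * q                        # newly transitioning in cycle t

    # Cycle-t rewards accrue to the state occupied at the cycle start (the
    # transition takes effect at the cycle boundary); the optional half-cycle
    # correction averages the boundary occupancies instead.
    occ_clz = 0.5 * (surv_prev + surv) if params.half_cycle_correction else surv_prev
    occ_sub = 1.0 - occ_clz

    t = np.arange(1, n + 1)
    df = (1.0 + country.annual_discount_rate) ** (-(t * cl / DAYS_PER_YEAR))

    drug = (occ_clz * country.clz_daily_cost + occ_sub * country.substitute_daily_cost) * cl
    monitoring = monitoring_cost_stream(country, True, n, cl) * occ_clz
    event = incident * country.ciag_treatment_cost
    hla_cost = country.hla_test_cost if strategy.hla_guided else 0.0

    cycle_years = cl / DAYS_PER_YEAR
    qalys = (occ_clz * country.utility_clz + occ_sub * country.utility_substitute) * cycle_years

    per_cycle_cost = drug + monitoring + event
    disc_cost = per_cycle_cost * df
    disc_qalys = qalys * df

    breakdown = {
        "drug": float(np.sum(drug * df)),
        "monitoring": float(np.sum(monitoring * df)),
        "ciag_event": float(np.sum(event * df)),
        "hla_test": hla_cost,
    }
    outcome = CEAOutcome(
        strategy=strategy,
        discounted_cost=float(np.sum(disc_cost)) + hla_cost,
        discounted_qalys=float(np.sum(disc_qalys)),
        undiscounted_cost=float(np.sum(per_cycle_cost)) + hla_cost,
        undiscounted_qalys=float(np.sum(qalys)),
        cost_breakdown=breakdown,
    )

    occupancy = np.column_stack(
        [np.concatenate([[1.0], surv]), np.concatenate([[0.0], 1.0 - surv])]
    )
    trace = CohortTrace(
        cycles=n,
        occupancy=occupancy,
        incident_ciag=incident,
        discounted_cost=np.concatenate([[hla_cost], disc_cost]),
        discounted_qalys=np.concatenate([[0.0], disc_qalys]),
    )
    return trace, outcome
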