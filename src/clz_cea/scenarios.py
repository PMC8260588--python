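"""Scenario grid over the six schedule options.

Three ANC discontinuation cutoffs (500/1000/1500 cells/mm^3) crossed with
HLA screening yes/no, per country: outcomes for every option,
guided-vs-unguided ICERs within each cutoff with a prevention-rate
sensitivity band, and the cost-effectiveness frontier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import pandas as pd

from ._slots import with_slot
from .config import VALID_CUTOFFS, ParameterSet, Strategy, round_gbp
from .engine import CEAOutcome, run_cohort
from .metrics import ComparisonResult, FrontierEntry, dominance_frontier, icer

#: Default prevention-rate sensitivity band for the grid's ICER parentheses.
DEFAULT_PREVENTION_BAND = (0.2, 0.8)


def enumerate_strategies() -> List[Strategy]:
    """The fixed 3x2 grid, cutoff ascending, unguided before guided."""
    return [
        Strategy(anc_cutoff=cutoff, hla_guided=guided)
        for cutoff in VALID_CUTOFFS
        for guided in (False, True)
    ]


@dataclass
class ScenarioGrid:
    country_id: str
    outcomes: Dict[str, CEAOutcome]              # keyed by strategy label
    comparisons: Dict[int, Dict[str, ComparisonResult]]
    frontier: List[FrontierEntry]
    prevention_band: Tuple[float, float]

    def outcome(self, strategy: Strategy) -> CEAOutcome:
        return self.outcomes[strategy.label]

    def to_table(self) -> pd.DataFrame:
        """Grid summary: one row per cutoff, guided/unguided cost and QALYs
        and the within-cutoff ICER with its prevention-band endpoints.

        Dominance quadrants carry the status string instead of a number (no
        ICER is calculated against a dominating option).
        """
        rows = []
        for cutoff in sorted(self.comparisons):
            comps = self.comparisons[cutoff]
            guided = self.outcomes[Strategy(anc_cutoff=cutoff, hla_guided=True).label]
            unguided = self.outcomes[Strategy(anc_cutoff=cutoff, hla_guided=False).label]

            def _icer_repr(comp: ComparisonResult):
                return comp.icer if comp.status == "icer" else comp.status

            rows.append(
                {
                    "cutoff": cutoff,
                    "cost_guided": round_gbp(guided.discounted_cost),
                    "cost_unguided": round_gbp(unguided.discounted_cost),
                    "qalys_guided": guided.discounted_qalys,
                    "qalys_unguided": unguided.discounted_qalys,
                    "icer": _icer_repr(comps["base"]),
                    "icer_prevention_low": _icer_repr(comps["prevention_low"]),
                    "icer_prevention_high": _icer_repr(comps["prevention_high"]),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "country": self.country_id,
            "prevention_band": list(self.prevention_band),
            "outcomes": {label: o.to_dict() for label, o in self.outcomes.items()},
            "comparisons": {
                str(cutoff): {key: comp.to_dict() for key, comp in comps.items()}
                for cutoff, comps in self.comparisons.items()
            },
            "frontier": [e.to_dict() for e in self.frontier],
        }


def explore(
    params: ParameterSet,
    prevention_band: Tuple[float, float] = DEFAULT_PREVENTION_BAND,
) -> ScenarioGrid:
    """Run all six schedule options and assemble the scenario grid.

    Requires onset curves for all three cutoffs.  Non-monotone cumulative
    incidence across cutoffs triggers a warning, not an error, so
    counterfactual curves can still be explored.
    """
    for cutoff in VALID_CUTOFFS:
        params.curve_for(cutoff)  # raises ConfigError when missing

    cums = [params.onset_curves[c].cumulative_incidence for c in VALID_CUTOFFS]
    if any(b < a for a, b in zip(cums, cums[1:])):
        warnings.warn(
            "cumulative CIAG incidence is not monotone in the ANC cutoff; "
            "proceeding (counterfactual exploration)",
            stacklevel=2,
        )

    wtp = params.country.wtp_threshold
    outcomes: Dict[str, CEAOutcome] = {}
    for strategy in enumerate_strategies():
        _, outcome = run_cohort(strategy, params)
        outcomes[strategy.label] = outcome

    lo, hi = prevention_band
    comparisons: Dict[int, Dict[str, ComparisonResult]] = {}
    for cutoff in VALID_CUTOFFS:
        guided = Strategy(anc_cutoff=cutoff, hla_guided=True)
        unguided = Strategy(anc_cutoff=cutoff, hla_guided=False)
        base_cmp = icer(outcomes[guided.label], outcomes[unguided.label], wtp=wtp)
        band: Dict[str, ComparisonResult] = {"base": base_cmp}
        for key, r in (("prevention_low", lo), ("prevention_high", hi)):
            p_band = with_slot(params, "prevention_rate", r)
            _, guided_out = run_cohort(guided, p_band)
            band[key] = icer(guided_out, outcomes[unguided.label], wtp=wtp)
        comparisons[cutoff] = band

    frontier = dominance_frontier(list(outcomes.values()))
    return ScenarioGrid(
        country_id=params.country.country_id,
        outcomes=outcomes,
        comparisons=comparisons,
        frontier=frontier,
        prevention_band=(lo, hi),
    )
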