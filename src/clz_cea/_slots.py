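"""Named scalar parameter slots on a ParameterSet.

Sensitivity analyses and the PSA address individual model parameters by
short names; this module maps those names to attribute paths and provides
copy-on-write get/set helpers.
"""

from __future__ import annotations

from typing import Dict

from pydantic import ValidationError

from .config import ConfigError, ParameterSet

#: slot name -> (sub-model attribute, field name)
SLOTS: Dict[str, tuple[str, str]] = {
    "prevention_rate": ("hla", "prevention_rate"),
    "ppv": ("hla", "ppv"),
    "test_sensitivity": ("hla", "test_sensitivity"),
    "phenotype_frequency": ("hla", "phenotype_frequency"),
    "ciag_treatment_cost": ("country", "ciag_treatment_cost"),
    "clz_daily_cost": ("country", "clz_daily_cost"),
    "substitute_daily_cost": ("country", "substitute_daily_cost"),
    "discount_rate": ("country", "annual_discount_rate"),
    "per_test_cost": ("country", "per_test_cost"),
    "hla_test_cost": ("country", "hla_test_cost"),
    "utility_clz": ("country", "utility_clz"),
    "utility_substitute": ("country", "utility_substitute"),
}

#: slots constrained to [0, 1] (probabilities, utilities, the discount rate)
PROBABILITY_SLOTS = frozenset(
    {
        "prevention_rate",
        "ppv",
        "test_sensitivity",
        "phenotype_frequency",
        "discount_rate",
        "utility_clz",
        "utility_substitute",
    }
)

#: non-negative currency slots
COST_SLOTS = frozenset(
    {
        "ciag_treatment_cost",
        "clz_daily_cost",
        "substitute_daily_cost",
        "per_test_cost",
        "hla_test_cost",
    }
)


def _resolve(name: str) -> tuple[str, str]:
    try:
        return SLOTS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter {name!r}; valid names: {', '.join(sorted(SLOTS))}"
        ) from None


def get_slot(params: ParameterSet, name: str) -> float:
    sub, attr = _resolve(name)
    return float(getattr(getattr(params, sub), attr))


def with_slot(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a deep copy of ``params`` with one slot replaced (re-validated)."""
    sub, attr = _resolve(name)
    out = params.model_copy(deep=True)
    try:
        setattr(getattr(out, sub), attr, value)
    except ValidationError as err:
        raise ConfigError(f"invalid value {value!r} for {name}: {err}") from err
    return out
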