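"""Parameter data model, configuration I/O, and report writing.

The model's inputs are literature-derived economic and epidemiological
parameters: a country profile (costs, utilities, discount rate, monitoring
schedule), HLA screening parameters (carrier frequency, test sensitivity,
PPV, the assumed CIAG prevention rate), and per-ANC-cutoff onset curves
giving the monthly probability of clozapine-induced agranulocytosis/
granulocytopenia (CIAG) conditional on still being on clozapine.

Configurations are single human-editable YAML files validated against the
pydantic schema defined here (``SCHEMA_VERSION`` = 1).  Costs are stored in
GBP at full double precision; rounding happens only at report boundaries.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

SCHEMA_VERSION = 1

#: Days per monthly model cycle (365.25 / 12).
DEFAULT_CYCLE_DAYS = 365.25 / 12.0

#: ANC discontinuation cutoffs (cells/mm^3) the model recognises.
VALID_CUTOFFS = (500, 1000, 1500)

#: Tolerance for the Hardy-Weinberg consistency check between a supplied
#: allele frequency and the phenotype (carrier) frequency.  The published
#: carrier rates are rounded to ~2 significant figures, hence the loose bound.
HARDY_WEINBERG_ATOL = 0.005


class ConfigError(ValueError):
    """A configuration file or ParameterSet violates the schema."""


class CountryProfile(BaseModel):
    """Country-level economics and monitoring schedule (all currency in GBP)."""

    model_config = ConfigDict(validate_assignment=True)

    country_id: Literal["JPN", "UK"]
    annual_discount_rate: float = Field(ge=0.0, lt=1.0)
    wtp_threshold: float = Field(ge=0.0, description="cost-per-QALY threshold, GBP")
    weekly_monitoring_weeks: int = Field(gt=0, description="weeks of weekly CBC monitoring")
    per_test_cost: float = Field(ge=0.0, description="cost of one blood test, GBP")
    ciag_treatment_cost: float = Field(ge=0.0, description="one-time CIAG episode cost, GBP")
    clz_daily_cost: float = Field(ge=0.0)
    substitute_daily_cost: float = Field(ge=0.0)
    hla_test_cost: float = Field(ge=0.0, description="one-time HLA typing cost, GBP (required)")
    utility_clz: float = Field(ge=0.0, le=1.0, description="utility/year on clozapine")
    utility_substitute: float = Field(ge=0.0, le=1.0, description="utility/year on substitute")
    jpy_per_gbp: float = Field(gt=0.0)


class HLAParameters(BaseModel):
    """HLA screening parameters under a dominant carrier model."""

    model_config = ConfigDict(validate_assignment=True)

    phenotype_frequency: float = Field(ge=0.0, le=1.0, description="carrier rate")
    test_sensitivity: float = Field(ge=0.0, le=1.0, description="P(carrier | CIAG)")
    ppv: float = Field(ge=0.0, le=1.0, description="P(CIAG | carrier)")
    prevention_rate: float = Field(ge=0.0, le=1.0, description="fraction of CIAG averted when HLA-guided")
    allele_frequency: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _hardy_weinberg_consistency(self) -> "HLAParameters":
        if self.allele_frequency is not None:
            expected = 1.0 - (1.0 - self.allele_frequency) ** 2
            if abs(expected - self.phenotype_frequency) > HARDY_WEINBERG_ATOL:
                raise ValueError(
                    f"phenotype_frequency={self.phenotype_frequency} inconsistent with "
                    f"Hardy-Weinberg 1-(1-AF)^2={expected:.6f} for AF={self.allele_frequency}"
                )
        return self


class OnsetCurve(BaseModel):
    """Per-cycle CIAG onset probabilities for one ANC cutoff.

    ``monthly_onset_prob[t]`` is the probability of CIAG onset during cycle
    ``t+1`` *conditional on still being on clozapine* at the cycle start.
    """

    model_config = ConfigDict(validate_assignment=True)

    cutoff: int
    monthly_onset_prob: List[float] = Field(min_length=1)

    @model_validator(mode="after")
    def _validate(self) -> "OnsetCurve":
        if self.cutoff not in VALID_CUTOFFS:
            raise ValueError(f"cutoff must be one of {VALID_CUTOFFS}, got {self.cutoff}")
        q = np.asarray(self.monthly_onset_prob, dtype=float)
        if np.any(q < 0.0) or np.any(q > 1.0):
            raise ValueError("monthly_onset_prob entries must lie in [0, 1]")
        return self

    @property
    def cumulative_incidence(self) -> float:
        """Total probability of CIAG over the curve's length."""
        return float(1.0 - np.prod(1.0 - np.asarray(self.monthly_onset_prob)))


class Strategy(BaseModel):
    """One treatment-schedule arm: ANC cutoff x whether HLA screening occurs."""

    model_config = ConfigDict(frozen=True)

    anc_cutoff: int
    hla_guided: bool

    @model_validator(mode="after")
    def _validate(self) -> "Strategy":
        if self.anc_cutoff not in VALID_CUTOFFS:
            raise ValueError(f"anc_cutoff must be one of {VALID_CUTOFFS}, got {self.anc_cutoff}")
        return self

    @property
    def label(self) -> str:
        return f"cutoff{self.anc_cutoff}_{'hla' if self.hla_guided else 'nohla'}"


class ParameterSet(BaseModel):
    """Complete model input for one country."""

    model_config = ConfigDict(validate_assignment=True)

    country: CountryProfile
    hla: HLAParameters
    onset_curves: Dict[int, OnsetCurve]
    horizon_years: float = Field(default=10.0, ge=1.0, le=50.0)
    cycle_length_days: float = Field(default=DEFAULT_CYCLE_DAYS, gt=0.0)
    half_cycle_correction: bool = False
    # Opt-in hook: derive the prevention rate from PPV (see engine module).
    derive_prevention_from_ppv: bool = False
    carrier_prevention_efficacy: float = Field(default=0.5, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "ParameterSet":
        if not self.onset_curves:
            raise ValueError("onset_curves must contain at least one cutoff")
        for cutoff, curve in self.onset_curves.items():
            if cutoff != curve.cutoff:
                raise ValueError(
                    f"onset_curves key {cutoff} does not match curve.cutoff {curve.cutoff}"
                )
        return self

    def curve_for(self, cutoff: int) -> OnsetCurve:
        try:
            return self.onset_curves[cutoff]
        except KeyError:
            raise ConfigError(
                f"no onset curve supplied for ANC cutoff {cutoff}; "
                f"available cutoffs: {sorted(self.onset_curves)}"
            ) from None


# ---------------------------------------------------------------------------
# currency helpers

def convert_jpy_to_gbp(amount_jpy: float, rate: float = 132.8, ndigits: int | None = 1) -> float:
    """Convert JPY to GBP at ``rate`` JPY per GBP.

    By default the result is rounded to 1 decimal, the convention used when
    reporting the cost-per-QALY threshold; pass ``ndigits=None`` for the raw
    quotient.
    """
    if rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {rate}")
    raw = amount_jpy / rate
    return raw if ndigits is None else round(raw, ndigits)


def daily_drug_cost(price_per_100mg: float, dose_mg: float, ndigits: int | None = 2) -> float:
    """Daily drug cost = unit price (per 100 mg) x daily dose, rounded for reporting."""
    if price_per_100mg < 0 or dose_mg < 0:
        raise ValueError("price and dose must be non-negative")
    raw = price_per_100mg * dose_mg / 100.0
    return raw if ndigits is None else round(raw, ndigits)


# ---------------------------------------------------------------------------
# file I/O

def _format_validation_error(err: ValidationError) -> str:
    parts = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        parts.append(f"{loc}: {e['msg']}")
    return "; ".join(parts)


def parameter_set_from_dict(data: dict) -> ParameterSet:
    """Build and validate a ParameterSet from a plain mapping."""
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    data = dict(data)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version} (expected {SCHEMA_VERSION})")
    try:
        return ParameterSet.model_validate(data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def parameter_set_to_dict(params: ParameterSet) -> dict:
    data = params.model_dump(mode="json")
    data["schema_version"] = SCHEMA_VERSION
    return data


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and validate a YAML configuration file into a ParameterSet."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as err:
            raise ConfigError(f"could not parse {path}: {err}") from err
    return parameter_set_from_dict(data)


def dump_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet to YAML; ``load_parameters`` round-trips it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameter_set_to_dict(params), fh, sort_keys=True)


def load_fixture(name: str) -> ParameterSet:
    """Load a bundled configuration fixture, e.g. ``japan_basecase``."""
    from importlib import resources

    ref = resources.files("clz_cea").joinpath("data", f"{name}.yaml")
    if not ref.is_file():
        raise ConfigError(f"no bundled fixture named {name!r}")
    return parameter_set_from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# report writing

def round_gbp(x: float) -> float:
    """Report-boundary rounding of currency to whole pounds."""
    return float(round(x))


def write_report(results, out_dir: str | Path) -> Dict[str, Path]:
    """Write a deterministic CSV + JSON report for a collection of results.

    ``results`` may mix comparison results and PSA results; each item must
    provide ``to_dict()`` (full-precision JSON payload) and may provide
    ``to_rows()`` (rows for the strategy/comparison CSV).
    """
    results = list(results)
    if not results:
        raise ValueError("write_report requires a non-empty collection of results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    payload = []
    for res in results:
        payload.append(res.to_dict())
        if hasattr(res, "to_rows"):
            rows.extend(res.to_rows())

    import pandas as pd

    paths: Dict[str, Path] = {}
    if rows:
        csv_path = out_dir / "comparisons.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        paths["csv"] = csv_path
    json_path = out_dir / "results.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    paths["json"] = json_path
    return paths
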