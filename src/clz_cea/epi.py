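"""Epidemiological and genetic calculators.

Hardy-Weinberg carrier (phenotype) frequency under a dominant risk model,
Bayes-theorem positive predictive value of HLA carriage for CIAG, and the
upper bound on the achievable CIAG prevention rate.
"""

from __future__ import annotations

from dataclasses import dataclass


def _check_proportion(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")


def phenotype_frequency(allele_frequency: float) -> float:
    """Carrier proportion 1 - (1 - AF)^2 under Hardy-Weinberg equilibrium.

    A carrier is homozygous or heterozygous for the risk allele (dominant
    model), so the carrier probability is p^2 + 2p(1-p) = 1 - (1-p)^2.
    """
    _check_proportion("allele_frequency", allele_frequency)
    return 1.0 - (1.0 - allele_frequency) ** 2


def carrier_ppv(
    test_sensitivity: float,
    ciag_cum_incidence: float,
    phenotype_frequency: float,
) -> float:
    """P(CIAG | carrier) by Bayes' theorem.

    ``test_sensitivity`` is P(carrier | CIAG); the PPV is then
    sensitivity x incidence / carrier frequency.  Incidence 0 yields PPV 0.
    """
    _check_proportion("test_sensitivity", test_sensitivity)
    _check_proportion("ciag_cum_incidence", ciag_cum_incidence)
    if ciag_cum_incidence == 0.0:
        return 0.0
    if not (0.0 < phenotype_frequency <= 1.0):
        raise ValueError(
            f"phenotype_frequency must lie in (0, 1], got {phenotype_frequency}"
        )
    if test_sensitivity * ciag_cum_incidence > phenotype_frequency:
        raise ValueError(
            "sensitivity x incidence exceeds the carrier frequency, which would "
            "imply P(CIAG | carrier) > 1; check the inputs"
        )
    return test_sensitivity * ciag_cum_incidence / phenotype_frequency


@dataclass(frozen=True)
class PreventionBound:
    """Upper bound on the overall CIAG prevention rate.

    ``max_prevention_rate`` is the product of the carrier sensitivity among
    preventable cases and the preventable-case share of all CIAG: even if
    every preventable event in a carrier were averted, only this fraction of
    all CIAG onsets could be prevented.
    """

    max_prevention_rate: float
    carrier_sensitivity_among_preventable: float
    preventable_share: float

    def __post_init__(self) -> None:
        expected = self.carrier_sensitivity_among_preventable * self.preventable_share
        if abs(self.max_prevention_rate - expected) > 1e-12:
            raise ValueError("max_prevention_rate must equal the product of its inputs")


def max_prevention_rate(
    carrier_sensitivity_among_preventable: float,
    preventable_share: float,
) -> PreventionBound:
    """Bound the overall prevention rate achievable by HLA screening."""
    _check_proportion(
        "carrier_sensitivity_among_preventable", carrier_sensitivity_among_preventable
    )
    _check_proportion("preventable_share", preventable_share)
    return PreventionBound(
        max_prevention_rate=carrier_sensitivity_among_preventable * preventable_share,
        carrier_sensitivity_among_preventable=carrier_sensitivity_among_preventable,
        preventable_share=preventable_share,
    )
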