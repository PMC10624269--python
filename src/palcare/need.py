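"""People in need of palliative care, by country and condition.

The need model is a linear decomposition of the mortality/prevalence
envelope: for each condition, the number of decedents in need is the
number of deaths times the condition's decedent need fraction, and
likewise for non-decedents with prevalent non-fatal cases.  No rounding
happens here — fractional persons are carried through and rounded only in
report tables.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .errors import NoDataError, ScenarioValidationError, ZeroNeedError
from .types import Condition, CountryRecord, NeedEstimate, Scenario

__all__ = ["estimate_need", "condition_shares", "regional_totals", "estimate_all_needs"]


def estimate_need(country: CountryRecord, conditions: Sequence[Condition]) -> NeedEstimate:
    """Estimate decedents and non-decedents in need for one country.

    Raises
    ------
    NoDataError
        If the country record is flagged ``data_available=False``.
    """
    if not country.data_available:
        raise NoDataError(f"no data available for {country.country!r}")
    by_code = {c.code: c for c in conditions}
    unknown = (set(country.decedent_deaths) | set(country.nondecedent_cases)) - set(by_code)
    if unknown:
        raise ScenarioValidationError(
            f"country {country.country!r} references unknown conditions {sorted(unknown)}")
    dec = {
        code: country.decedent_deaths.get(code, 0.0) * by_code[code].decedent_need_fraction
        for code in by_code
    }
    nondec = {
        code: country.nondecedent_cases.get(code, 0.0) * by_code[code].nondecedent_need_fraction
        for code in by_code
    }
    return NeedEstimate(country=country.country,
                        decedents_in_need=dec, nondecedents_in_need=nondec)


def estimate_all_needs(scenario: Scenario) -> list[NeedEstimate]:
    """Need estimates for every country with data, in scenario order."""
    return [estimate_need(c, scenario.conditions) for c in scenario.countries_with_data()]


def condition_shares(estimate: NeedEstimate) -> dict[str, float]:
    """Percentage of a country's total need generated by each condition.

    Shares sum to 100 across conditions.  Raises
    :class:`~palcare.errors.ZeroNeedError` if the country has nobody in
    need.
    """
    total = estimate.grand_total
    if total <= 0:
        raise ZeroNeedError(f"{estimate.country!r} has zero palliative care need")
    codes = set(estimate.decedents_in_need) | set(estimate.nondecedents_in_need)
    return {
        code: 100.0
        * (estimate.decedents_in_need.get(code, 0.0)
           + estimate.nondecedents_in_need.get(code, 0.0))
        / total
        for code in sorted(codes)
    }


def regional_totals(estimates: Iterable[NeedEstimate],
                    label: str = "Total") -> NeedEstimate:
    """Elementwise sum of need estimates across countries.

    Countries without data never produce a :class:`NeedEstimate`, so they
    are excluded upstream.  Raises a validation error on an empty input.
    """
    estimates = list(estimates)
    if not estimates:
        raise ScenarioValidationError("regional_totals requires at least one estimate")
    dec: dict[str, float] = {}
    nondec: dict[str, float] = {}
    for est in estimates:
        for code, v in est.decedents_in_need.items():
            dec[code] = dec.get(code, 0.0) + v
        for code, v in est.nondecedents_in_need.items():
            nondec[code] = nondec.get(code, 0.0) + v
    return NeedEstimate(country=label, decedents_in_need=dec, nondecedents_in_need=nondec)
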