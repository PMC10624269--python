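"""Symptom-day burden bounds.

A symptom-day is one day on which one person experiences one moderate or
severe symptom.  Because co-occurrence of symptoms within a patient-day
is unknown, the burden is bracketed:

* the **at-most** bound adds together N x prevalence x duration over every
  symptom associated with each (condition, status) cell — it counts each
  symptom's days separately even when they overlap in calendar time;
* the **at-least** bound keeps only the symptom of longest duration per
  (condition, status) cell — the minimum number of distinct suffering
  days consistent with the coefficients.

By default the at-least bound is prevalence-weighted like the upper
bound; setting ``at_least_weighting="unit"`` in the scenario options
treats the longest symptom as universal instead.  Duration ties are
broken by higher prevalence, then lexicographic symptom label, so the
bound is deterministic.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .errors import ScenarioValidationError, ZeroBurdenError
from .types import NeedEstimate, Scenario, SymptomBurden, SymptomCoefficient
from .vocab import STATUSES

__all__ = ["symptom_burden", "symptom_shares", "estimate_all_burdens"]


def _rows_by_cell(
    coefficients: Sequence[SymptomCoefficient],
) -> dict[tuple[str, str], list[SymptomCoefficient]]:
    cells: dict[tuple[str, str], list[SymptomCoefficient]] = {}
    for row in coefficients:
        cells.setdefault((row.condition, row.status), []).append(row)
    return cells


def symptom_burden(
    estimate: NeedEstimate,
    coefficients: Sequence[SymptomCoefficient],
    at_least_weighting: str = "prevalence",
) -> SymptomBurden:
    """Compute both symptom-day bounds for one country.

    Every (condition, status) cell with people in need must have at least
    one coefficient row; a cell with no rows and nobody in need simply
    contributes zero.
    """
    cells = _rows_by_cell(coefficients)
    at_most = 0.0
    at_least = 0.0
    per_symptom: dict[str, float] = {}

    for status in STATUSES:
        counts = (estimate.decedents_in_need if status == "decedent"
                  else estimate.nondecedents_in_need)
        for condition, n in counts.items():
            if n == 0:
                continue
            rows = cells.get((condition, status))
            if rows is None:
                raise ScenarioValidationError(
                    f"no symptom coefficients for condition {condition!r}, "
                    f"status {status!r} but {estimate.country!r} has people in need",
                    table="symptom_coefficients.csv")
            for row in rows:
                days = n * row.prevalence * row.duration_days
                at_most += days
                per_symptom[row.symptom] = per_symptom.get(row.symptom, 0.0) + days
            # longest duration wins; ties by higher prevalence then label
            longest = max(rows, key=lambda r: (r.duration_days, r.prevalence, r.symptom))
            weight = longest.prevalence if at_least_weighting == "prevalence" else 1.0
            at_least += n * weight * longest.duration_days

    return SymptomBurden(country=estimate.country, at_least_days=at_least,
                         at_most_days=at_most, per_symptom_days=per_symptom)


def estimate_all_burdens(scenario: Scenario,
                         needs: Iterable[NeedEstimate]) -> list[SymptomBurden]:
    """Symptom-day bounds for every need estimate, using scenario options."""
    return [
        symptom_burden(est, scenario.symptom_coefficients,
                       scenario.options.at_least_weighting)
        for est in needs
    ]


def symptom_shares(burden: SymptomBurden) -> dict[str, float]:
    """Percentage of a country's at-most symptom days due to each symptom.

    Raises :class:`~palcare.errors.ZeroBurdenError` when the country has
    zero symptom days.
    """
    if burden.at_most_days <= 0:
        raise ZeroBurdenError(f"{burden.country!r} has zero symptom days")
    return {
        symptom: 100.0 * days / burden.at_most_days
        for symptom, days in sorted(burden.per_symptom_days.items())
    }
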