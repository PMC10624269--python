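"""Workforce requirements: encounter days, FTEs, FTEs per 100,000.

Patients in need are converted to encounter volumes (inpatient days and
outpatient visits at four facility levels, home visits at the home
level) through per-patient encounter coefficients, and encounter volumes
to staff full-time equivalents through staffing norms expressed in
staff-hours per encounter unit:

    FTE(category, level) = (inpatient_days(level) * h_ipd
                            + outpatient_visits(level) * h_opv
                            + home_visits * h_hv, home only) / annual_fte_hours

Everything is linear in patient counts, so totals are additive over
conditions, levels and countries.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .errors import ScenarioValidationError
from .rounding import round_half_up
from .types import (
    EncounterCoefficient,
    NeedEstimate,
    Scenario,
    StaffingNorm,
    WorkforceEstimate,
)
from .vocab import CARE_LEVELS, FACILITY_LEVELS, STAFF_CATEGORIES, STATUSES, CareLevel

__all__ = [
    "encounter_totals", "staff_fte", "fte_per_100k",
    "workforce_summary_range", "estimate_workforce", "estimate_all_workforce",
]


def encounter_totals(
    need: NeedEstimate,
    coefficients: Sequence[EncounterCoefficient],
) -> tuple[dict[str, float], dict[str, float], float]:
    """Aggregate per-level inpatient days, outpatient visits, home visits.

    Returns ``(inpatient_days, outpatient_visits, home_visits)`` with the
    first two keyed by facility level.  A (condition, status) cell with
    people in need but no coefficient rows contributes zero encounters;
    coefficient coverage is a scenario design choice, not an error.
    """
    by_cell: dict[tuple[str, str], list[EncounterCoefficient]] = {}
    for row in coefficients:
        by_cell.setdefault((row.condition, row.status), []).append(row)

    inpatient = {level: 0.0 for level in FACILITY_LEVELS}
    outpatient = {level: 0.0 for level in FACILITY_LEVELS}
    home_visits = 0.0
    for status in STATUSES:
        counts = (need.decedents_in_need if status == "decedent"
                  else need.nondecedents_in_need)
        for condition, n in counts.items():
            if n == 0:
                continue
            for row in by_cell.get((condition, status), []):
                if row.level == CareLevel.home:
                    home_visits += n * row.home_visits_per_patient
                else:
                    inpatient[row.level.value] += n * row.inpatient_days_per_patient
                    outpatient[row.level.value] += n * row.outpatient_visits_per_patient
    return inpatient, outpatient, home_visits


def staff_fte(
    inpatient_days: dict[str, float],
    outpatient_visits: dict[str, float],
    home_visits: float,
    norms: Sequence[StaffingNorm],
) -> dict[str, dict[str, float]]:
    """FTEs per staff category and care level from encounter volumes.

    Categories or levels without a norm row require zero staff there.
    """
    fte: dict[str, dict[str, float]] = {
        cat: {level: 0.0 for level in CARE_LEVELS} for cat in STAFF_CATEGORIES
    }
    for norm in norms:
        level = norm.level.value
        if level == CareLevel.home.value:
            hours = home_visits * norm.hours_per_home_visit
        else:
            hours = (inpatient_days.get(level, 0.0) * norm.hours_per_inpatient_day
                     + outpatient_visits.get(level, 0.0) * norm.hours_per_outpatient_visit)
        fte[norm.staff_category][level] += hours / norm.annual_fte_hours
    return fte


def fte_per_100k(total_fte: float, population: int) -> float:
    """FTEs per 100,000 population, reported to 2 decimals (half-up)."""
    if population <= 0:
        raise ScenarioValidationError(f"population must be > 0, got {population}")
    return round_half_up(100_000.0 * total_fte / population, 2)


def estimate_workforce(need: NeedEstimate, population: int,
                       coefficients: Sequence[EncounterCoefficient],
                       norms: Sequence[StaffingNorm]) -> WorkforceEstimate:
    """Full workforce estimate for one country."""
    if population <= 0:
        raise ScenarioValidationError(
            f"population must be > 0 for {need.country!r}, got {population}")
    inpatient, outpatient, home_visits = encounter_totals(need, coefficients)
    fte = staff_fte(inpatient, outpatient, home_visits, norms)
    return WorkforceEstimate(
        country=need.country,
        population=population,
        decedents=need.decedent_total,
        nondecedents=need.nondecedent_total,
        inpatient_days=inpatient,
        outpatient_visits=outpatient,
        home_visits=home_visits,
        fte_by_level=fte,
    )


def estimate_all_workforce(scenario: Scenario,
                           needs: Iterable[NeedEstimate]) -> list[WorkforceEstimate]:
    """Workforce estimates for every need estimate in the scenario."""
    populations = {c.country: c.population for c in scenario.countries_with_data()}
    return [
        estimate_workforce(est, populations[est.country],
                           scenario.encounter_coefficients, scenario.staffing_norms)
        for est in needs
    ]


def workforce_summary_range(estimates: Sequence[WorkforceEstimate],
                            category: str) -> tuple[float, float]:
    """(min, max) FTE per 100k across countries, to 1 decimal (half-up)."""
    if not estimates:
        raise ScenarioValidationError("workforce_summary_range requires estimates")
    values = [est.fte_per_100k(category) for est in estimates]
    return round_half_up(min(values), 1), round_half_up(max(values), 1)
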