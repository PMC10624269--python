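"""Opioid access metrics: DOME, per-patient DOME, requirement, percent met.

DOME — distributed-opioid oral morphine equivalents — is the quantity of
strong opioids other than methadone distributed in a country, converted
to oral morphine milligrams through an equianalgesic table.  Methadone is
excluded because its distribution is dominated by opioid-agonist therapy
rather than analgesia.  DOME per patient in need is a surrogate for
palliative care accessibility.

The modelled requirement is the amount of oral morphine needed to treat
every patient in need who has moderate or severe pain (a daily dose over
the pain duration) or refractory terminal dyspnea (a daily dose over the
dyspnea duration, decedents only).  Percent of need met is
100 x DOME / requirement and is deliberately uncapped.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .errors import ScenarioValidationError, ZeroNeedError, ZeroRequirementError
from .types import (
    EquianalgesicFactor,
    NeedEstimate,
    OpioidAccess,
    OpioidSupplyRecord,
    RequirementParams,
    Scenario,
    SymptomCoefficient,
)
from .vocab import STATUSES

__all__ = [
    "to_ome", "dome_per_patient", "required_ome", "percent_need_met",
    "opioid_access", "estimate_all_access",
]

PAIN_SYMPTOM = "pain"
DYSPNEA_SYMPTOM = "dyspnea"


def to_ome(supply: Iterable[OpioidSupplyRecord],
           table: Sequence[EquianalgesicFactor]) -> dict[str, float]:
    """Convert per-product supplies to per-country oral morphine mg.

    Methadone rows contribute zero; any other product without an
    equianalgesic factor raises a validation error naming it.
    """
    factors = {(f.opioid, f.route_class): f for f in table}
    dome: dict[str, float] = {}
    for rec in supply:
        dome.setdefault(rec.country, 0.0)
        factor = factors.get((rec.opioid, rec.route_class))
        if factor is None:
            raise ScenarioValidationError(
                f"no equianalgesic factor for opioid {rec.opioid!r} "
                f"({rec.route_class})", table="equianalgesic.csv")
        if factor.is_methadone:
            continue
        dome[rec.country] += rec.quantity_mg * factor.ome_multiplier
    return dome


def dome_per_patient(dome_mg: float, need: NeedEstimate) -> float:
    """Oral morphine mg available per patient in need of palliative care."""
    total = need.grand_total
    if total <= 0:
        raise ZeroNeedError(f"{need.country!r} has zero patients in need")
    return dome_mg / total


def required_ome(need: NeedEstimate,
                 coefficients: Sequence[SymptomCoefficient],
                 params: RequirementParams) -> float:
    """Oral morphine mg required to treat pain and terminal dyspnea.

    The pain term covers decedents and non-decedents (or decedents only
    when ``params.requirement_population == "decedents"``); the terminal
    dyspnea term covers decedents only.  Conditions whose coefficient
    table carries no pain or dyspnea row contribute nothing through that
    term.
    """
    lookup = {(r.condition, r.symptom, r.status): r for r in coefficients}
    required = 0.0
    for status in STATUSES:
        counts = (need.decedents_in_need if status == "decedent"
                  else need.nondecedents_in_need)
        include_pain = status == "decedent" or params.requirement_population == "all"
        include_dyspnea = status == "decedent"
        for condition, n in counts.items():
            if n == 0:
                continue
            if include_pain:
                row = lookup.get((condition, PAIN_SYMPTOM, status))
                if row is not None:
                    required += (n * row.prevalence * row.duration_days
                                 * params.pain_daily_dose_mg)
            if include_dyspnea:
                row = lookup.get((condition, DYSPNEA_SYMPTOM, status))
                if row is not None:
                    required += (n * row.prevalence * row.duration_days
                                 * params.dyspnea_daily_dose_mg)
    return required


def percent_need_met(dome_mg: float, required_mg: float) -> float:
    """Percent of the modelled opioid requirement covered by DOME (uncapped)."""
    if required_mg <= 0:
        raise ZeroRequirementError("modelled opioid requirement is zero")
    return 100.0 * dome_mg / required_mg


def opioid_access(need: NeedEstimate, dome_mg: float,
                  coefficients: Sequence[SymptomCoefficient],
                  params: RequirementParams,
                  procedural_fraction: float = 0.0) -> OpioidAccess:
    """Assemble the full access record for one country."""
    dome = dome_mg * (1.0 - procedural_fraction)
    required = required_ome(need, coefficients, params)
    return OpioidAccess(
        country=need.country,
        dome_mg=dome,
        dome_per_patient_mg=dome_per_patient(dome, need),
        required_mg=required,
        percent_met=percent_need_met(dome, required),
    )


def estimate_all_access(scenario: Scenario,
                        needs: Iterable[NeedEstimate]) -> list[OpioidAccess]:
    """Opioid access metrics for every need estimate in the scenario."""
    dome = to_ome(scenario.opioid_supply, scenario.equianalgesic_table)
    return [
        opioid_access(est, dome.get(est.country, 0.0),
                      scenario.symptom_coefficients,
                      scenario.requirement_params,
                      scenario.options.procedural_fraction)
        for est in needs
    ]
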