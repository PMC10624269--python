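"""Independent brute-force reference implementations.

Deliberately naive nested loops over (country, condition, status,
symptom/level) with no shared code with the package internals; the test
suite checks the pipeline against these to 1e-9 relative tolerance.
"""

from __future__ import annotations

from palcare.types import Scenario
from palcare.vocab import FACILITY_LEVELS, STAFF_CATEGORIES


def need_by_country(scenario: Scenario) -> dict[str, dict]:
    out = {}
    fractions = {(c.code, "decedent"): c.decedent_need_fraction for c in scenario.conditions}
    fractions |= {(c.code, "nondecedent"): c.nondecedent_need_fraction
                  for c in scenario.conditions}
    for rec in scenario.countries:
        if not rec.data_available:
            continue
        dec, nondec = {}, {}
        for cond in scenario.conditions:
            dec[cond.code] = rec.decedent_deaths.get(cond.code, 0.0) * fractions[
                (cond.code, "decedent")]
            nondec[cond.code] = rec.nondecedent_cases.get(cond.code, 0.0) * fractions[
                (cond.code, "nondecedent")]
        out[rec.country] = {"decedent": dec, "nondecedent": nondec,
                            "total": sum(dec.values()) + sum(nondec.values())}
    return out


def symptom_days(scenario: Scenario, needs: dict[str, dict]) -> dict[str, dict]:
    """At-most / at-least bounds (prevalence-weighted lower bound)."""
    out = {}
    for country, need in needs.items():
        at_most = 0.0
        at_least = 0.0
        per_symptom: dict[str, float] = {}
        for status in ("decedent", "nondecedent"):
            for cond, n in need[status].items():
                if n == 0:
                    continue
                rows = [r for r in scenario.symptom_coefficients
                        if r.condition == cond and r.status == status]
                best = None
                for r in rows:
                    days = n * r.prevalence * r.duration_days
                    at_most += days
                    per_symptom[r.symptom] = per_symptom.get(r.symptom, 0.0) + days
                    if best is None or (r.duration_days, r.prevalence, r.symptom) > (
                            best.duration_days, best.prevalence, best.symptom):
                        best = r
                if best is not None:
                    at_least += n * best.prevalence * best.duration_days
        out[country] = {"at_most": at_most, "at_least": at_least,
                        "per_symptom": per_symptom}
    return out


def dome(scenario: Scenario) -> dict[str, float]:
    factors = {(f.opioid, f.route_class): f for f in scenario.equianalgesic_table}
    out: dict[str, float] = {}
    for rec in scenario.opioid_supply:
        f = factors[(rec.opioid, rec.route_class)]
        out.setdefault(rec.country, 0.0)
        if not f.is_methadone:
            out[rec.country] += rec.quantity_mg * f.ome_multiplier
    return out


def required_mg(scenario: Scenario, needs: dict[str, dict]) -> dict[str, float]:
    params = scenario.requirement_params
    coeff = {(r.condition, r.symptom, r.status): r
             for r in scenario.symptom_coefficients}
    out = {}
    for country, need in needs.items():
        total = 0.0
        for status in ("decedent", "nondecedent"):
            for cond, n in need[status].items():
                if n == 0:
                    continue
                if status == "decedent" or params.requirement_population == "all":
                    r = coeff.get((cond, "pain", status))
                    if r:
                        total += n * r.prevalence * r.duration_days * params.pain_daily_dose_mg
                if status == "decedent":
                    r = coeff.get((cond, "dyspnea", status))
                    if r:
                        total += (n * r.prevalence * r.duration_days
                                  * params.dyspnea_daily_dose_mg)
        out[country] = total
    return out


def encounters(scenario: Scenario, needs: dict[str, dict]) -> dict[str, dict]:
    out = {}
    for country, need in needs.items():
        inpatient = {lv: 0.0 for lv in FACILITY_LEVELS}
        outpatient = {lv: 0.0 for lv in FACILITY_LEVELS}
        home = 0.0
        for status in ("decedent", "nondecedent"):
            for cond, n in need[status].items():
                for row in scenario.encounter_coefficients:
                    if row.condition != cond or row.status != status:
                        continue
                    if row.level.value == "home":
                        home += n * row.home_visits_per_patient
                    else:
                        inpatient[row.level.value] += n * row.inpatient_days_per_patient
                        outpatient[row.level.value] += n * row.outpatient_visits_per_patient
        out[country] = {"inpatient": inpatient, "outpatient": outpatient,
                        "home": home}
    return out


def ftes(scenario: Scenario, enc: dict[str, dict]) -> dict[str, dict[str, float]]:
    out = {}
    for country, e in enc.items():
        totals = {cat: 0.0 for cat in STAFF_CATEGORIES}
        for norm in scenario.staffing_norms:
            if norm.level.value == "home":
                hours = e["home"] * norm.hours_per_home_visit
            else:
                hours = (e["inpatient"][norm.level.value] * norm.hours_per_inpatient_day
                         + e["outpatient"][norm.level.value]
                         * norm.hours_per_outpatient_visit)
            totals[norm.staff_category] += hours / norm.annual_fte_hours
        out[country] = totals
    return out
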