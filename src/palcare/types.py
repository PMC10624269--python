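"""Domain types for scenario inputs and pipeline results.

Input types are pydantic models so that field-level bounds (fractions in
[0, 1], non-negative counts, positive divisors) are enforced at
construction time.  Cross-record invariants — dangling condition codes,
duplicate coefficient rows, allocation shares that do not sum to one —
are checked by :meth:`Scenario.validate`, which raises
:class:`~palcare.errors.ScenarioValidationError` naming the offending
table and row.

Result types (:class:`NeedEstimate`, :class:`SymptomBurden`,
:class:`OpioidAccess`, :class:`WorkforceEstimate`) keep full float
precision; rounding is applied only when a report table is written.
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ScenarioValidationError
from .vocab import (
    CARE_LEVELS,
    CONDITION_CODES,
    FACILITY_LEVELS,
    INCOME_GROUPS,
    STAFF_CATEGORIES,
    STATUSES,
    SYMPTOMS,
    CareLevel,
)

RouteClass = Literal["oral", "parenteral", "transdermal"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


# ---------------------------------------------------------------------------
# scenario input records
# ---------------------------------------------------------------------------

class Condition(_Model):
    """A serious-illness condition and its palliative care need fractions.

    ``decedent_need_fraction`` is the proportion of people who die of the
    condition in the reference year who need palliative care;
    ``nondecedent_need_fraction`` is the analogous proportion among people
    living with the condition who do not die of it that year.
    """

    code: str
    name: str
    decedent_need_fraction: float = Field(ge=0.0, le=1.0)
    nondecedent_need_fraction: float = Field(ge=0.0, le=1.0)


class CountryRecord(_Model):
    """One country's population and cause-specific caseload envelopes.

    ``decedent_deaths`` maps condition code to deaths in the reference
    year; ``nondecedent_cases`` maps condition code to prevalent non-fatal
    cases.  A record with ``data_available=False`` carries no counts and is
    excluded from every aggregate (it still appears in report tables as
    "No data").
    """

    country: str
    income_group: Literal["low", "lower-middle", "upper-middle", "high"]
    population: int | None = None
    decedent_deaths: dict[str, float] = Field(default_factory=dict)
    nondecedent_cases: dict[str, float] = Field(default_factory=dict)
    data_available: bool = True

    @model_validator(mode="after")
    def _check(self) -> "CountryRecord":
        if self.data_available:
            if self.population is None or self.population <= 0:
                raise ValueError(
                    f"country {self.country!r}: population must be > 0 when data_available"
                )
            for name, counts in (("decedent_deaths", self.decedent_deaths),
                                 ("nondecedent_cases", self.nondecedent_cases)):
                for code, v in counts.items():
                    if v < 0:
                        raise ValueError(
                            f"country {self.country!r}: negative {name}[{code}]"
                        )
        else:
            if self.decedent_deaths or self.nondecedent_cases:
                raise ValueError(
                    f"country {self.country!r}: data_available=False but counts present"
                )
        return self


class SymptomCoefficient(_Model):
    """Prevalence and mean duration of one symptom for one condition/status.

    ``source`` distinguishes coefficients stated in the underlying evidence
    base (``"reported"``) from documented placeholder defaults
    (``"assumed"``); the pipeline treats both identically but the flag is
    preserved through round-trips so users can audit and substitute them.
    """

    condition: str
    symptom: str
    status: Literal["decedent", "nondecedent"]
    prevalence: float = Field(ge=0.0, le=1.0)
    duration_days: float = Field(ge=0.0)
    source: Literal["reported", "assumed"] = "assumed"


class OpioidSupplyRecord(_Model):
    """Quantity of one opioid product distributed in one country (mg)."""

    country: str
    opioid: str
    route_class: RouteClass
    quantity_mg: float = Field(ge=0.0)


class EquianalgesicFactor(_Model):
    """mg of oral morphine analgesically equivalent to 1 mg of a product."""

    opioid: str
    route_class: RouteClass
    ome_multiplier: float = Field(gt=0.0)
    is_methadone: bool = False


class RequirementParams(_Model):
    """Dosing assumptions behind the modelled opioid requirement.

    ``pain_daily_dose_mg`` is the oral morphine equivalent per day assumed
    to adequately treat moderate or severe pain; ``dyspnea_daily_dose_mg``
    the daily dose for refractory terminal dyspnea.
    ``requirement_population`` selects whether the pain term covers all
    patients in need or decedents only; the terminal-dyspnea term always
    covers decedents only.
    """

    pain_daily_dose_mg: float = Field(default=67.5, gt=0.0)
    dyspnea_daily_dose_mg: float = Field(default=10.0, gt=0.0)
    requirement_population: Literal["all", "decedents"] = "all"


class EncounterCoefficient(_Model):
    """Per-patient encounter intensities at one care level.

    Home visits are only meaningful at the ``home`` level; inpatient days
    and outpatient visits only at facility levels.  The constructor
    enforces that split.
    """

    condition: str
    status: Literal["decedent", "nondecedent"]
    level: CareLevel
    inpatient_days_per_patient: float = Field(default=0.0, ge=0.0)
    outpatient_visits_per_patient: float = Field(default=0.0, ge=0.0)
    home_visits_per_patient: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "EncounterCoefficient":
        if self.level == CareLevel.home:
            if self.inpatient_days_per_patient or self.outpatient_visits_per_patient:
                raise ValueError(
                    "home level carries only home visits "
                    f"(condition={self.condition}, status={self.status})"
                )
        elif self.home_visits_per_patient:
            raise ValueError(
                f"home visits declared at facility level {self.level.value} "
                f"(condition={self.condition}, status={self.status})"
            )
        return self


class StaffingNorm(_Model):
    """Staff-hours generated per encounter unit, for one category at one level."""

    staff_category: str
    level: CareLevel
    hours_per_inpatient_day: float = Field(default=0.0, ge=0.0)
    hours_per_outpatient_visit: float = Field(default=0.0, ge=0.0)
    hours_per_home_visit: float = Field(default=0.0, ge=0.0)
    annual_fte_hours: float = Field(default=1650.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "StaffingNorm":
        if self.staff_category not in STAFF_CATEGORIES:
            raise ValueError(f"unknown staff category {self.staff_category!r}")
        return self


class LevelAllocation(_Model):
    """Share of encounter volume assigned to one care level for an income group.

    The allocation profile is an explicit scenario input because the split
    of palliative care across system levels is a planning choice, not a
    published constant; the synthetic generator uses it to derive
    per-condition encounter coefficients.
    """

    income_group: Literal["low", "lower-middle", "upper-middle", "high"]
    level: CareLevel
    share: float = Field(ge=0.0, le=1.0)


class ModelOptions(_Model):
    """Documented switches for the points where the method is underdetermined.

    at_least_weighting:
        Whether the lower symptom-day bound weights the longest-duration
        symptom by its prevalence (``"prevalence"``, default) or assumes
        every patient experiences it (``"unit"``).
    procedural_fraction:
        Fraction of distributed opioids assumed consumed by surgical or
        procedural use and subtracted from DOME before access metrics are
        computed.  Default 0 (no correction).
    """

    at_least_weighting: Literal["prevalence", "unit"] = "prevalence"
    procedural_fraction: float = Field(default=0.0, ge=0.0, le=1.0)


# ---------------------------------------------------------------------------
# the scenario bundle
# ---------------------------------------------------------------------------

class Scenario(_Model):
    """The complete input bundle one pipeline run consumes."""

    reference_year: int = 2015
    conditions: list[Condition]
    countries: list[CountryRecord]
    symptom_coefficients: list[SymptomCoefficient]
    opioid_supply: list[OpioidSupplyRecord] = Field(default_factory=list)
    equianalgesic_table: list[EquianalgesicFactor] = Field(default_factory=list)
    requirement_params: RequirementParams = Field(default_factory=RequirementParams)
    encounter_coefficients: list[EncounterCoefficient] = Field(default_factory=list)
    staffing_norms: list[StaffingNorm] = Field(default_factory=list)
    level_allocation: list[LevelAllocation] = Field(default_factory=list)
    options: ModelOptions = Field(default_factory=ModelOptions)

    # -- convenience lookups ------------------------------------------------

    @property
    def condition_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.conditions)

    def condition(self, code: str) -> Condition:
        for c in self.conditions:
            if c.code == code:
                return c
        raise KeyError(code)

    def country(self, name: str) -> CountryRecord:
        for rec in self.countries:
            if rec.country == name:
                return rec
        raise KeyError(name)

    def countries_with_data(self) -> list[CountryRecord]:
        return [c for c in self.countries if c.data_available]

    # -- cross-record invariants -------------------------------------------

    def validate(self) -> "Scenario":
        """Check cross-record invariants; raise ScenarioValidationError.

        Field-level bounds are already guaranteed by the pydantic models;
        this method checks uniqueness and referential integrity across
        tables.
        """
        codes = [c.code for c in self.conditions]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ScenarioValidationError(
                f"duplicate condition codes {dupes}", table="conditions.csv")
        code_set = set(codes)

        names = [c.country for c in self.countries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ScenarioValidationError(
                f"duplicate countries {dupes}", table="countries.csv")
        name_set = set(names)

        for i, rec in enumerate(self.countries):
            for code in set(rec.decedent_deaths) | set(rec.nondecedent_cases):
                if code not in code_set:
                    raise ScenarioValidationError(
                        f"country {rec.country!r} references undeclared condition {code!r}",
                        table="countries.csv", row=i)

        seen: set[tuple[str, str, str]] = set()
        for i, sc in enumerate(self.symptom_coefficients):
            if sc.condition not in code_set:
                raise ScenarioValidationError(
                    f"undeclared condition {sc.condition!r}",
                    table="symptom_coefficients.csv", row=i, field="condition")
            if sc.symptom not in SYMPTOMS:
                raise ScenarioValidationError(
                    f"unknown symptom {sc.symptom!r}",
                    table="symptom_coefficients.csv", row=i, field="symptom")
            key = (sc.condition, sc.symptom, sc.status)
            if key in seen:
                raise ScenarioValidationError(
                    f"duplicate coefficient row for {key}",
                    table="symptom_coefficients.csv", row=i)
            seen.add(key)

        factors = {(f.opioid, f.route_class) for f in self.equianalgesic_table}
        for i, rec in enumerate(self.opioid_supply):
            if rec.country not in name_set:
                raise ScenarioValidationError(
                    f"undeclared country {rec.country!r}",
                    table="opioid_supply.csv", row=i, field="country")
            if (rec.opioid, rec.route_class) not in factors:
                raise ScenarioValidationError(
                    f"no equianalgesic factor for ({rec.opioid!r}, {rec.route_class!r})",
                    table="opioid_supply.csv", row=i, field="opioid")

        seen_ec: set[tuple[str, str, str]] = set()
        for i, ec in enumerate(self.encounter_coefficients):
            if ec.condition not in code_set:
                raise ScenarioValidationError(
                    f"undeclared condition {ec.condition!r}",
                    table="encounter_coefficients.csv", row=i, field="condition")
            key = (ec.condition, ec.status, ec.level.value)
            if key in seen_ec:
                raise ScenarioValidationError(
                    f"duplicate encounter coefficient for {key}",
                    table="encounter_coefficients.csv", row=i)
            seen_ec.add(key)

        seen_norm: set[tuple[str, str]] = set()
        for i, norm in enumerate(self.staffing_norms):
            key = (norm.staff_category, norm.level.value)
            if key in seen_norm:
                raise ScenarioValidationError(
                    f"duplicate staffing norm for {key}",
                    table="staffing_norms.csv", row=i)
            seen_norm.add(key)

        by_group: dict[str, float] = {}
        for alloc in self.level_allocation:
            by_group[alloc.income_group] = by_group.get(alloc.income_group, 0.0) + alloc.share
        for group, total in by_group.items():
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ScenarioValidationError(
                    f"level allocation shares for income group {group!r} sum to "
                    f"{total}, expected 1",
                    table="level_allocation.csv", field="share")
        return self


# ---------------------------------------------------------------------------
# pipeline results
# ---------------------------------------------------------------------------

class NeedEstimate(_Model):
    """Per-condition counts of people needing palliative care in one country.

    Counts are fractional persons; totals are derived, so the invariant
    "totals equal sums of per-condition values" holds by construction.
    """

    country: str
    decedents_in_need: dict[str, float]
    nondecedents_in_need: dict[str, float]

    @property
    def decedent_total(self) -> float:
        return sum(self.decedents_in_need.values())

    @property
    def nondecedent_total(self) -> float:
        return sum(self.nondecedents_in_need.values())

    @property
    def grand_total(self) -> float:
        return self.decedent_total + self.nondecedent_total

    def in_need(self, condition: str, status: str) -> float:
        m = self.decedents_in_need if status == "decedent" else self.nondecedents_in_need
        return m.get(condition, 0.0)


class SymptomBurden(_Model):
    """At-least/at-most symptom-day bounds for one country.

    ``per_symptom_days`` is the at-most accounting grouped by symptom, so
    it sums to ``at_most_days``.
    """

    country: str
    at_least_days: float
    at_most_days: float
    per_symptom_days: dict[str, float]


class OpioidAccess(_Model):
    """Opioid accessibility metrics for one country.

    ``dome_mg`` is the distributed-opioid oral morphine equivalents;
    ``percent_met`` is uncapped (supplies exceeding modelled need report
    values above 100).
    """

    country: str
    dome_mg: float = Field(ge=0.0)
    dome_per_patient_mg: float = Field(ge=0.0)
    required_mg: float = Field(ge=0.0)
    percent_met: float = Field(ge=0.0)


class WorkforceEstimate(_Model):
    """Encounter volumes and staffing requirements for one country."""

    country: str
    population: int
    decedents: float
    nondecedents: float
    inpatient_days: dict[str, float]
    outpatient_visits: dict[str, float]
    home_visits: float
    fte_by_level: dict[str, dict[str, float]]

    @property
    def total_patients(self) -> float:
        return self.decedents + self.nondecedents

    def fte_total(self, category: str) -> float:
        return sum(self.fte_by_level[category].values())

    def fte_per_100k(self, category: str) -> float:
        return 100_000.0 * self.fte_total(category) / self.population


__all__ = [
    "Condition", "CountryRecord", "SymptomCoefficient", "OpioidSupplyRecord",
    "EquianalgesicFactor", "RequirementParams", "EncounterCoefficient",
    "StaffingNorm", "LevelAllocation", "ModelOptions", "Scenario",
    "NeedEstimate", "SymptomBurden", "OpioidAccess", "WorkforceEstimate",
    "RouteClass", "CareLevel", "CARE_LEVELS", "FACILITY_LEVELS",
    "CONDITION_CODES", "INCOME_GROUPS", "STAFF_CATEGORIES", "STATUSES",
    "SYMPTOMS",
]
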