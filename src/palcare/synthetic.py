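"""Synthetic scenario generator.

Real runs of this pipeline consume national cause-of-death envelopes,
narcotics-board opioid distribution data and health-system staffing
norms.  None of those can be redistributed here, so this module
generates complete, internally consistent scenarios with the same
statistical structure: about 21 countries stratified into four income
groups, 20 serious-illness conditions with income-group-specific cause
mixes (optionally including one HIV-dominated low-income country),
deaths roughly proportional to population, 15-symptom coefficient
tables honouring every prevalence/duration the evidence base states,
and opioid supplies planted at a known fraction of the modelled
requirement per income group (spanning well under 1% to above 100% of
need).

Everything is a deterministic function of the seed, and planted
quantities (need fraction x deaths; supply fraction of requirement) are
recoverable exactly by the downstream pipeline, which is what makes the
generator usable as a closed-loop test harness.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ScenarioValidationError
from .need import estimate_need
from .opioids import required_ome
from .types import (
    Condition,
    CountryRecord,
    EncounterCoefficient,
    EquianalgesicFactor,
    LevelAllocation,
    ModelOptions,
    NeedEstimate,
    OpioidSupplyRecord,
    RequirementParams,
    Scenario,
    StaffingNorm,
    SymptomCoefficient,
)
from .vocab import (
    CARE_LEVELS,
    CONDITION_CODES,
    FACILITY_LEVELS,
    INCOME_GROUPS,
    STAFF_CATEGORIES,
    SYMPTOMS,
    CareLevel,
)

__all__ = [
    "GeneratorSpec", "make_default_conditions", "make_default_coefficients",
    "make_default_equianalgesic_table", "make_default_staffing_norms",
    "make_default_level_allocation", "simulate_mortality",
    "simulate_opioid_supply", "make_scenario",
]


# ---------------------------------------------------------------------------
# generator specification
# ---------------------------------------------------------------------------

#: countries per income group in the default region (21 with data).
_DEFAULT_N_COUNTRIES = {"low": 3, "lower-middle": 7, "upper-middle": 5, "high": 6}

#: opioid supply as a planted fraction of the modelled requirement.
_DEFAULT_SUPPLY_TARGETS = {
    "low": 0.005, "lower-middle": 0.05, "upper-middle": 0.5, "high": 1.2,
}

#: population draw range (persons) per income group.
_POPULATION_RANGES = {
    "low": (8_000_000, 45_000_000),
    "lower-middle": (5_000_000, 200_000_000),
    "upper-middle": (4_000_000, 85_000_000),
    "high": (1_200_000, 36_000_000),
}

#: relative cause-mix weights over conditions, by income group.  Low-income
#: mixes lean toward infectious disease, maternal/child conditions and
#: injuries; high-income mixes toward neoplasms, dementia and circulatory
#: disease.  Per-country mixes jitter around these.
_CONDITION_WEIGHTS: dict[str, dict[str, float]] = {
    "low": {
        "hiv": 8, "tb": 8, "injuries": 12, "prematurity": 8, "malnutrition": 6,
        "congenital": 5, "hemorrhagic_fevers": 2, "neoplasms": 10, "leukemia": 1,
        "cerebrovascular": 7, "dementia": 2, "cihd": 8, "nihd": 5, "lung": 5,
        "liver": 4, "renal": 3, "cns_inflammatory": 2, "cns_degenerative": 1,
        "musculoskeletal": 2, "atherosclerosis": 1,
    },
    "lower-middle": {
        "hiv": 4, "tb": 5, "injuries": 11, "prematurity": 5, "malnutrition": 3,
        "congenital": 4, "hemorrhagic_fevers": 1, "neoplasms": 15, "leukemia": 2,
        "cerebrovascular": 9, "dementia": 4, "cihd": 11, "nihd": 6, "lung": 6,
        "liver": 5, "renal": 3, "cns_inflammatory": 1, "cns_degenerative": 1,
        "musculoskeletal": 2, "atherosclerosis": 2,
    },
    "upper-middle": {
        "hiv": 2, "tb": 2, "injuries": 10, "prematurity": 3, "malnutrition": 1,
        "congenital": 3, "hemorrhagic_fevers": 0.5, "neoplasms": 19, "leukemia": 2,
        "cerebrovascular": 10, "dementia": 7, "cihd": 13, "nihd": 7, "lung": 7,
        "liver": 4, "renal": 3, "cns_inflammatory": 1, "cns_degenerative": 1.5,
        "musculoskeletal": 2, "atherosclerosis": 2,
    },
    "high": {
        "hiv": 0.5, "tb": 0.5, "injuries": 8, "prematurity": 2, "malnutrition": 0.5,
        "congenital": 2, "hemorrhagic_fevers": 0.1, "neoplasms": 24, "leukemia": 3,
        "cerebrovascular": 9, "dementia": 12, "cihd": 14, "nihd": 8, "lung": 8,
        "liver": 3, "renal": 3, "cns_inflammatory": 0.5, "cns_degenerative": 2,
        "musculoskeletal": 2, "atherosclerosis": 2,
    },
}

#: HIV-dominated override mix (one low-income country on request).
_HIV_DOMINATED_WEIGHTS = {code: 1.0 for code in CONDITION_CODES} | {"hiv": 60.0}


class GeneratorSpec(BaseModel):
    """Parameters of the synthetic region.

    ``population_scale`` multiplies every drawn population (death counts
    scale along with it); ``supply_targets`` plants the per-income-group
    opioid supply as a fraction of the modelled requirement;
    ``hiv_dominated_country`` makes the first low-income country's cause
    mix HIV-dominated.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    reference_year: int = 2015
    n_countries: dict[str, int] = Field(
        default_factory=lambda: dict(_DEFAULT_N_COUNTRIES))
    condition_weights: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(w) for g, w in _CONDITION_WEIGHTS.items()})
    hiv_dominated_country: bool = True
    include_no_data_country: bool = False
    population_scale: float = Field(default=1.0, gt=0.0)
    crude_death_rate: float = Field(default=0.007, gt=0.0, lt=1.0)
    serious_illness_death_share: float = Field(default=0.45, gt=0.0, le=1.0)
    nondecedent_case_ratio: float = Field(default=2.0, gt=0.0)
    supply_targets: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_SUPPLY_TARGETS))

    @model_validator(mode="after")
    def _check(self) -> "GeneratorSpec":
        for group in self.n_countries:
            if group not in INCOME_GROUPS:
                raise ValueError(f"unknown income group {group!r}")
        for group, weights in self.condition_weights.items():
            if group not in INCOME_GROUPS:
                raise ValueError(f"unknown income group {group!r}")
            for code, w in weights.items():
                if code not in CONDITION_CODES:
                    raise ValueError(f"unknown condition code {code!r}")
                if w < 0:
                    raise ValueError(
                        f"negative condition weight {w} for {code!r} in {group!r}")
        for group, f in self.supply_targets.items():
            if group not in INCOME_GROUPS:
                raise ValueError(f"unknown income group {group!r}")
            if f < 0:
                raise ValueError(f"negative supply target {f} for {group!r}")
        return self


# ---------------------------------------------------------------------------
# default coefficient tables
# ---------------------------------------------------------------------------

#: decedent need fraction by condition (proportion of deaths generating
#: palliative care need); non-decedent fractions are lower because many
#: prevalent cases are mild or controlled.
_DECEDENT_NEED_FRACTIONS = {
    "hiv": 0.90, "neoplasms": 0.85, "leukemia": 0.85, "cerebrovascular": 0.60,
    "dementia": 0.95, "cihd": 0.40, "nihd": 0.45, "lung": 0.80, "liver": 0.70,
    "renal": 0.60, "tb": 0.80, "cns_inflammatory": 0.60, "cns_degenerative": 0.90,
    "musculoskeletal": 0.50, "injuries": 0.35, "hemorrhagic_fevers": 0.50,
    "malnutrition": 0.60, "congenital": 0.70, "prematurity": 0.60,
    "atherosclerosis": 0.40,
}
_NONDECEDENT_NEED_FRACTIONS = {
    code: round(f * 0.4, 3) for code, f in _DECEDENT_NEED_FRACTIONS.items()
}


def make_default_conditions() -> list[Condition]:
    """The 20-condition framework with default need fractions."""
    from .vocab import CONDITIONS

    return [
        Condition(code=code, name=name,
                  decedent_need_fraction=_DECEDENT_NEED_FRACTIONS[code],
                  nondecedent_need_fraction=_NONDECEDENT_NEED_FRACTIONS[code])
        for code, name in CONDITIONS.items()
    ]


#: base decedent (prevalence, mean duration in days) per symptom, used for
#: every cell the evidence base does not pin down; flagged "assumed".
_BASE_DECEDENT = {
    "pain": (0.60, 80.0),
    "dyspnea": (0.30, 30.0),
    "fatigue": (0.70, 90.0),
    "weakness": (0.60, 80.0),
    "nausea_or_vomiting": (0.25, 20.0),
    "diarrhea": (0.15, 15.0),
    "constipation": (0.25, 25.0),
    "dry_mouth": (0.20, 20.0),
    "pruritus": (0.10, 15.0),
    "wounds_or_bleeding": (0.10, 20.0),
    "oral_lesions": (0.10, 15.0),
    "anxiety_or_worry": (0.55, 60.0),
    "depressed_mood": (0.45, 55.0),
    "confusion_or_delirium": (0.30, 15.0),
    "dementia_symptoms": (0.05, 30.0),
}

#: cells the evidence base states explicitly: (condition, symptom, status)
#: -> (prevalence, duration_days).  Moderate/severe pain affects 80% of
#: cancer decedents for an average of three months; terminal dyspnea is
#: near-universal in chronic lung disease, 75-80% in heart disease
#: (midpoint 0.775 used), 70% in HIV/AIDS, 50% in liver disease and in
#: prematurity/birth trauma.
_REPORTED_CELLS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("neoplasms", "pain", "decedent"): (0.80, 90.0),
    ("leukemia", "pain", "decedent"): (0.80, 90.0),
    ("lung", "dyspnea", "decedent"): (1.00, 30.0),
    ("cihd", "dyspnea", "decedent"): (0.775, 30.0),
    ("nihd", "dyspnea", "decedent"): (0.775, 30.0),
    ("hiv", "dyspnea", "decedent"): (0.70, 30.0),
    ("liver", "dyspnea", "decedent"): (0.50, 30.0),
    ("prematurity", "dyspnea", "decedent"): (0.50, 30.0),
}

#: assumed (not reported) condition-specific overrides for face validity.
_ASSUMED_CELLS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("dementia", "dementia_symptoms", "decedent"): (0.85, 120.0),
    ("dementia", "dementia_symptoms", "nondecedent"): (0.85, 150.0),
    ("hiv", "pain", "decedent"): (0.70, 75.0),
    ("injuries", "pain", "decedent"): (0.70, 30.0),
    ("liver", "pain", "decedent"): (0.65, 60.0),
    ("musculoskeletal", "pain", "decedent"): (0.70, 120.0),
    ("congenital", "pain", "decedent"): (0.65, 60.0),
    ("prematurity", "pain", "decedent"): (0.65, 14.0),
}

#: non-decedent cells default to lower prevalence, same duration.
_NONDECEDENT_PREVALENCE_FACTOR = 0.5


def make_default_coefficients() -> list[SymptomCoefficient]:
    """Symptom coefficient table for all 20 conditions x 15 symptoms x 2 statuses.

    Cells with an explicitly stated prevalence/duration are flagged
    ``source="reported"``; every other cell carries a documented placeholder
    (``source="assumed"``) that users can substitute with better evidence.
    """
    rows: list[SymptomCoefficient] = []
    for condition in CONDITION_CODES:
        for symptom in SYMPTOMS:
            base_p, base_d = _BASE_DECEDENT[symptom]
            for status in ("decedent", "nondecedent"):
                key = (condition, symptom, status)
                if key in _REPORTED_CELLS:
                    p, d = _REPORTED_CELLS[key]
                    source = "reported"
                elif key in _ASSUMED_CELLS:
                    p, d = _ASSUMED_CELLS[key]
                    source = "assumed"
                elif status == "nondecedent":
                    dec_key = (condition, symptom, "decedent")
                    dp, dd = _REPORTED_CELLS.get(dec_key) or _ASSUMED_CELLS.get(
                        dec_key) or (base_p, base_d)
                    p, d = dp * _NONDECEDENT_PREVALENCE_FACTOR, dd
                    source = "assumed"
                else:
                    p, d = base_p, base_d
                    source = "assumed"
                rows.append(SymptomCoefficient(
                    condition=condition, symptom=symptom, status=status,
                    prevalence=p, duration_days=d, source=source))
    return rows


def make_default_equianalgesic_table() -> list[EquianalgesicFactor]:
    """Standard equianalgesic factors (mg oral morphine per mg product)."""
    return [
        EquianalgesicFactor(opioid="morphine", route_class="oral",
                            ome_multiplier=1.0),
        EquianalgesicFactor(opioid="morphine", route_class="parenteral",
                            ome_multiplier=3.0),
        EquianalgesicFactor(opioid="oxycodone", route_class="oral",
                            ome_multiplier=1.5),
        EquianalgesicFactor(opioid="hydromorphone", route_class="oral",
                            ome_multiplier=4.0),
        EquianalgesicFactor(opioid="fentanyl", route_class="transdermal",
                            ome_multiplier=100.0),
        EquianalgesicFactor(opioid="methadone", route_class="oral",
                            ome_multiplier=4.0, is_methadone=True),
    ]


#: (hours per inpatient day, hours per outpatient visit) by staff category
#: at facility levels, and hours per home visit at the home level.
_FACILITY_HOURS = {
    "doctor": (0.50, 0.50),
    "nurse": (2.00, 0.75),
    "social_worker": (0.50, 0.40),
    "spiritual_counsellor": (0.10, 0.05),
    "psychologist_or_psychiatrist": (0.08, 0.05),
    "physical_therapist": (0.03, 0.02),
    "pharmacist": (0.12, 0.10),
    "community_health_worker": (0.0, 0.0),
    "clinical_support": (0.02, 0.01),
    "nonclinical_support": (0.15, 0.05),
}
_HOME_VISIT_HOURS = {
    "community_health_worker": 1.00,
    "nurse": 0.05,
    "social_worker": 0.05,
    "doctor": 0.01,
}
_ANNUAL_FTE_HOURS = 1650.0


def make_default_staffing_norms() -> list[StaffingNorm]:
    """Default staff-hours per encounter unit for all 10 categories."""
    norms: list[StaffingNorm] = []
    for cat in STAFF_CATEGORIES:
        ipd, opv = _FACILITY_HOURS[cat]
        for level in FACILITY_LEVELS:
            norms.append(StaffingNorm(
                staff_category=cat, level=CareLevel(level),
                hours_per_inpatient_day=ipd, hours_per_outpatient_visit=opv,
                annual_fte_hours=_ANNUAL_FTE_HOURS))
        hv = _HOME_VISIT_HOURS.get(cat, 0.0)
        norms.append(StaffingNorm(
            staff_category=cat, level=CareLevel.home,
            hours_per_home_visit=hv, annual_fte_hours=_ANNUAL_FTE_HOURS))
    return norms


_LEVEL_ALLOCATION = {
    "low": {"referral_hospital": 0.10, "provincial_hospital": 0.10,
            "district_hospital": 0.20, "community_health_center": 0.15,
            "home": 0.45},
    "lower-middle": {"referral_hospital": 0.12, "provincial_hospital": 0.13,
                     "district_hospital": 0.22, "community_health_center": 0.18,
                     "home": 0.35},
    "upper-middle": {"referral_hospital": 0.18, "provincial_hospital": 0.17,
                     "district_hospital": 0.25, "community_health_center": 0.15,
                     "home": 0.25},
    "high": {"referral_hospital": 0.25, "provincial_hospital": 0.20,
             "district_hospital": 0.25, "community_health_center": 0.10,
             "home": 0.20},
}


def make_default_level_allocation() -> list[LevelAllocation]:
    """Default share of care volume at each level, by income group."""
    return [
        LevelAllocation(income_group=group, level=CareLevel(level), share=share)
        for group, profile in _LEVEL_ALLOCATION.items()
        for level, share in profile.items()
    ]


#: per-patient encounter intensities before level allocation.
_ENCOUNTER_BASE = {
    "decedent": {"inpatient_days": 14.0, "outpatient_visits": 8.0,
                 "home_visits": 100.0},
    "nondecedent": {"inpatient_days": 4.0, "outpatient_visits": 6.0,
                    "home_visits": 45.0},
}


def _blended_allocation(allocation: list[LevelAllocation]) -> dict[str, float]:
    """Unweighted mean of the income-group profiles over the five levels."""
    sums = {level: 0.0 for level in CARE_LEVELS}
    groups = {a.income_group for a in allocation}
    for a in allocation:
        sums[a.level.value] += a.share
    return {level: v / len(groups) for level, v in sums.items()}


def make_default_encounter_coefficients(
    allocation: list[LevelAllocation] | None = None,
) -> list[EncounterCoefficient]:
    """Per-patient encounter coefficients for every condition/status/level.

    The scenario-wide coefficient table is built from base per-patient
    intensities split across levels by the blended allocation profile
    (the coefficient table is shared by all countries; group-specific
    tables can be generated by passing a single-group allocation).
    """
    allocation = allocation or make_default_level_allocation()
    shares = _blended_allocation(allocation)
    rows: list[EncounterCoefficient] = []
    for condition in CONDITION_CODES:
        for status, base in _ENCOUNTER_BASE.items():
            for level in FACILITY_LEVELS:
                rows.append(EncounterCoefficient(
                    condition=condition, status=status, level=CareLevel(level),
                    inpatient_days_per_patient=base["inpatient_days"] * shares[level],
                    outpatient_visits_per_patient=base["outpatient_visits"] * shares[level],
                ))
            rows.append(EncounterCoefficient(
                condition=condition, status=status, level=CareLevel.home,
                home_visits_per_patient=base["home_visits"] * shares["home"]))
    return rows


# ---------------------------------------------------------------------------
# stochastic pieces
# ---------------------------------------------------------------------------

_GROUP_ABBREV = {"low": "LIC", "lower-middle": "LMIC",
                 "upper-middle": "UMIC", "high": "HIC"}


def simulate_mortality(spec: GeneratorSpec) -> list[CountryRecord]:
    """Draw country populations and per-condition deaths/prevalent cases.

    Deaths scale with population (crude death rate x serious-illness share
    x per-country condition mix); non-decedent prevalent cases are drawn
    directly as a jittered per-condition multiple of deaths.  Fully
    deterministic given ``spec.seed``.
    """
    spec = GeneratorSpec.model_validate(spec)
    rng = np.random.default_rng(spec.seed)
    records: list[CountryRecord] = []
    for group in INCOME_GROUPS:
        n = spec.n_countries.get(group, 0)
        lo, hi = _POPULATION_RANGES[group]
        base_weights = spec.condition_weights.get(group, _CONDITION_WEIGHTS[group])
        for i in range(n):
            name = f"{_GROUP_ABBREV[group]}-{i + 1}"
            base_pop = rng.integers(lo, hi)
            population = max(1, int(round(base_pop * spec.population_scale)))
            hiv_dominated = (spec.hiv_dominated_country and group == "low" and i == 0)
            weights = dict(_HIV_DOMINATED_WEIGHTS) if hiv_dominated else dict(base_weights)
            w = np.array([weights.get(code, 0.0) for code in CONDITION_CODES])
            w = w * rng.lognormal(mean=0.0, sigma=0.25, size=w.size)
            mix = w / w.sum()
            cdr = spec.crude_death_rate * rng.lognormal(mean=0.0, sigma=0.15)
            death_rates = cdr * spec.serious_illness_death_share * mix
            deaths = {
                code: float(round(population * rate))
                for code, rate in zip(CONDITION_CODES, death_rates)
            }
            ratios = spec.nondecedent_case_ratio * rng.lognormal(
                mean=0.0, sigma=0.3, size=len(CONDITION_CODES))
            cases = {
                code: float(round(deaths[code] * ratio))
                for code, ratio in zip(CONDITION_CODES, ratios)
            }
            records.append(CountryRecord(
                country=name, income_group=group, population=population,
                decedent_deaths=deaths, nondecedent_cases=cases))
    if spec.include_no_data_country:
        records.append(CountryRecord(
            country="NoData-1", income_group="lower-middle",
            data_available=False))
    return records


#: non-methadone products the planted supply is decomposed across.
_SUPPLY_PRODUCTS = (
    ("morphine", "oral", 1.0),
    ("oxycodone", "oral", 1.5),
    ("fentanyl", "transdermal", 100.0),
)


def simulate_opioid_supply(
    spec: GeneratorSpec,
    needs: list[NeedEstimate],
    requirement_mg: dict[str, float],
    income_groups: dict[str, str],
) -> list[OpioidSupplyRecord]:
    """Plant per-country supplies at the income-group target fraction of need.

    Each country's DOME target (fraction x modelled requirement) is split
    across three non-methadone products with a random Dirichlet
    decomposition, plus a methadone quantity that downstream conversion
    must ignore.  Seeded separately from mortality so the decomposition
    varies with the seed while totals stay planted.
    """
    spec = GeneratorSpec.model_validate(spec)
    rng = np.random.default_rng((spec.seed, 7919))  # decoupled opioid stream
    records: list[OpioidSupplyRecord] = []
    for est in needs:
        group = income_groups[est.country]
        fraction = spec.supply_targets.get(group, 0.0)
        dome_target = fraction * requirement_mg[est.country]
        shares = rng.dirichlet(np.ones(len(_SUPPLY_PRODUCTS)))
        for (opioid, route, multiplier), share in zip(_SUPPLY_PRODUCTS, shares):
            records.append(OpioidSupplyRecord(
                country=est.country, opioid=opioid, route_class=route,
                quantity_mg=dome_target * share / multiplier))
        records.append(OpioidSupplyRecord(
            country=est.country, opioid="methadone", route_class="oral",
            quantity_mg=float(rng.uniform(1e5, 1e6))))
    return records


def make_scenario(spec: GeneratorSpec | None = None, *,
                  seed: int | None = None) -> Scenario:
    """Generate a complete valid Scenario from a generator spec.

    ``make_scenario(seed=7)`` is shorthand for a default spec with that
    seed.  The returned scenario passes full validation and closes the
    loop: running the pipeline on it recovers the planted need fractions
    and supply fractions exactly.
    """
    if spec is None:
        spec = GeneratorSpec(seed=seed if seed is not None else 0)
    elif seed is not None:
        spec = spec.model_copy(update={"seed": seed})
    try:
        spec = GeneratorSpec.model_validate(spec)
    except ValueError as exc:
        raise ScenarioValidationError(f"invalid generator spec: {exc}") from exc

    conditions = make_default_conditions()
    coefficients = make_default_coefficients()
    countries = simulate_mortality(spec)
    allocation = make_default_level_allocation()
    requirement_params = RequirementParams()

    with_data = [c for c in countries if c.data_available]
    needs = [estimate_need(c, conditions) for c in with_data]
    requirement = {
        est.country: required_ome(est, coefficients, requirement_params)
        for est in needs
    }
    income_groups = {c.country: c.income_group for c in with_data}
    supply = simulate_opioid_supply(spec, needs, requirement, income_groups)

    scenario = Scenario(
        reference_year=spec.reference_year,
        conditions=conditions,
        countries=countries,
        symptom_coefficients=coefficients,
        opioid_supply=supply,
        equianalgesic_table=make_default_equianalgesic_table(),
        requirement_params=requirement_params,
        encounter_coefficients=make_default_encounter_coefficients(allocation),
        staffing_norms=make_default_staffing_norms(),
        level_allocation=allocation,
        options=ModelOptions(),
    )
    return scenario.validate()
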