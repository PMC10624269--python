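"""Shared fixtures: the default synthetic region and small random scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from palcare import GeneratorSpec, Scenario, make_scenario
from palcare.synthetic import (
    make_default_equianalgesic_table,
    make_default_staffing_norms,
)
from palcare.types import (
    Condition,
    CountryRecord,
    EncounterCoefficient,
    OpioidSupplyRecord,
    SymptomCoefficient,
)
from palcare.vocab import (
    CONDITION_CODES,
    FACILITY_LEVELS,
    INCOME_GROUPS,
    SYMPTOMS,
    CareLevel,
)

#: a small region for tests that run the full generator repeatedly.
SMALL_N_COUNTRIES = {"low": 1, "lower-middle": 2, "upper-middle": 1, "high": 1}


@pytest.fixture(scope="session")
def default_scenario() -> Scenario:
    """The default 21-country synthetic region, seed 1."""
    return make_scenario(GeneratorSpec(seed=1))


@pytest.fixture()
def small_spec() -> GeneratorSpec:
    return GeneratorSpec(seed=1, n_countries=dict(SMALL_N_COUNTRIES))


def random_small_scenario(seed: int) -> Scenario:
    """A tiny random scenario built directly (independent of the generator).

    2-5 countries, 3-6 conditions, random coefficients everywhere; used to
    compare the pipeline against the brute-force oracle.
    """
    rng = np.random.default_rng(seed)
    n_cond = int(rng.integers(3, 7))
    codes = list(rng.choice(CONDITION_CODES, size=n_cond, replace=False))
    conditions = [
        Condition(code=code, name=code,
                  decedent_need_fraction=float(rng.uniform(0.2, 1.0)),
                  nondecedent_need_fraction=float(rng.uniform(0.0, 0.6)))
        for code in codes
    ]

    n_countries = int(rng.integers(2, 6))
    countries = []
    for i in range(n_countries):
        countries.append(CountryRecord(
            country=f"C{i}",
            income_group=str(rng.choice(INCOME_GROUPS)),
            population=int(rng.integers(100_000, 50_000_000)),
            decedent_deaths={c: float(rng.integers(0, 20_000)) for c in codes},
            nondecedent_cases={c: float(rng.integers(0, 40_000)) for c in codes},
        ))

    coefficients = []
    for code in codes:
        for status in ("decedent", "nondecedent"):
            symptoms = set(rng.choice(SYMPTOMS, size=int(rng.integers(2, 6)),
                                      replace=False))
            symptoms.add("pain")  # keeps the opioid requirement positive
            for symptom in sorted(symptoms):
                coefficients.append(SymptomCoefficient(
                    condition=code, symptom=str(symptom), status=status,
                    prevalence=float(rng.uniform(0.05, 1.0)),
                    duration_days=float(rng.uniform(1.0, 180.0))))

    equianalgesic = make_default_equianalgesic_table()
    supply = []
    for rec in countries:
        for factor in equianalgesic:
            if rng.random() < 0.7:
                supply.append(OpioidSupplyRecord(
                    country=rec.country, opioid=factor.opioid,
                    route_class=factor.route_class,
                    quantity_mg=float(rng.uniform(0, 5e6))))

    encounter = []
    for code in codes:
        for status in ("decedent", "nondecedent"):
            for level in FACILITY_LEVELS:
                encounter.append(EncounterCoefficient(
                    condition=code, status=status, level=CareLevel(level),
                    inpatient_days_per_patient=float(rng.uniform(0, 5)),
                    outpatient_visits_per_patient=float(rng.uniform(0, 5))))
            encounter.append(EncounterCoefficient(
                condition=code, status=status, level=CareLevel.home,
                home_visits_per_patient=float(rng.uniform(0, 30))))

    return Scenario(
        conditions=conditions,
        countries=countries,
        symptom_coefficients=coefficients,
        opioid_supply=supply,
        equianalgesic_table=equianalgesic,
        encounter_coefficients=encounter,
        staffing_norms=make_default_staffing_norms(),
    ).validate()
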