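"""Encounter totals, FTE conversion, per-100k normalization and ranges."""

import pytest

from palcare import (
    encounter_totals,
    estimate_all_needs,
    estimate_all_workforce,
    fte_per_100k,
    staff_fte,
    workforce_summary_range,
)
from palcare.errors import ScenarioValidationError
from palcare.types import EncounterCoefficient, NeedEstimate, StaffingNorm, WorkforceEstimate
from palcare.vocab import CareLevel

from .conftest import random_small_scenario
from . import oracle


def _need(n=100.0):
    return NeedEstimate(country="X", decedents_in_need={"neoplasms": n},
                        nondecedents_in_need={})


def test_encounter_totals_direct_product():
    rows = [EncounterCoefficient(condition="neoplasms", status="decedent",
                                 level=CareLevel.district_hospital,
                                 inpatient_days_per_patient=2.0,
                                 outpatient_visits_per_patient=1.5),
            EncounterCoefficient(condition="neoplasms", status="decedent",
                                 level=CareLevel.home, home_visits_per_patient=10.0)]
    inpatient, outpatient, home = encounter_totals(_need(100.0), rows)
    assert inpatient["district_hospital"] == pytest.approx(200.0)
    assert outpatient["district_hospital"] == pytest.approx(150.0)
    assert home == pytest.approx(1000.0)


def test_zero_patients_zero_encounters():
    rows = [EncounterCoefficient(condition="neoplasms", status="decedent",
                                 level=CareLevel.referral_hospital,
                                 inpatient_days_per_patient=5.0)]
    inpatient, outpatient, home = encounter_totals(_need(0.0), rows)
    assert sum(inpatient.values()) == sum(outpatient.values()) == home == 0.0


def test_staff_fte_hours_over_annual_hours():
    norms = [StaffingNorm(staff_category="nurse",
                          level=CareLevel.district_hospital,
                          hours_per_inpatient_day=1.0, annual_fte_hours=1650.0)]
    fte = staff_fte({"district_hospital": 1650.0}, {}, 0.0, norms)
    assert fte["nurse"]["district_hospital"] == pytest.approx(1.0)
    assert fte["doctor"]["district_hospital"] == 0.0


def test_fte_doubling_hours_doubles_fte_doubling_annual_halves():
    base = StaffingNorm(staff_category="nurse", level=CareLevel.home,
                        hours_per_home_visit=0.5, annual_fte_hours=1650.0)
    double_hours = base.model_copy(update={"hours_per_home_visit": 1.0})
    double_year = base.model_copy(update={"annual_fte_hours": 3300.0})
    f = lambda norm: staff_fte({}, {}, 10_000.0, [norm])["nurse"]["home"]
    assert f(double_hours) == pytest.approx(2 * f(base))
    assert f(double_year) == pytest.approx(f(base) / 2)


def test_fte_per_100k_published_arithmetic():
    assert fte_per_100k(722, 38_928_340) == 1.85
    assert fte_per_100k(554, 10_203_140) == 5.43
    assert fte_per_100k(0, 5_000_000) == 0.0


def test_fte_per_100k_rejects_nonpositive_population():
    with pytest.raises(ScenarioValidationError):
        fte_per_100k(10, 0)


def _estimate_with_fte(country, population, fte):
    from palcare.vocab import STAFF_CATEGORIES

    zero_levels = {lv.value: 0.0 for lv in CareLevel if lv != CareLevel.home}
    fte_by_level = {cat: {"home": float(fte.get(cat, 0.0))}
                    for cat in STAFF_CATEGORIES}
    return WorkforceEstimate(country=country, population=population,
                             decedents=0.0, nondecedents=0.0,
                             inpatient_days=zero_levels, outpatient_visits=zero_levels,
                             home_visits=0.0, fte_by_level=fte_by_level)


def test_summary_range_published_chw_and_nurse_bands():
    estimates = [
        _estimate_with_fte("Afghanistan", 38_928_340,
                           {"community_health_worker": 3018, "nurse": 1443}),
        _estimate_with_fte("Morocco", 36_910_560,
                           {"community_health_worker": 4096, "nurse": 1588}),
        _estimate_with_fte("Jordan", 10_203_140,
                           {"community_health_worker": 554, "nurse": 222}),
    ]
    assert workforce_summary_range(estimates, "community_health_worker") == (5.4, 11.1)
    assert workforce_summary_range(estimates, "nurse") == (2.2, 4.3)


def test_summary_range_single_country_min_equals_max():
    est = _estimate_with_fte("A", 1_000_000, {"doctor": 10})
    assert workforce_summary_range([est], "doctor") == (1.0, 1.0)


def test_summary_range_empty_raises():
    with pytest.raises(ScenarioValidationError):
        workforce_summary_range([], "doctor")


@pytest.mark.parametrize("seed", range(10))
def test_workforce_matches_bruteforce_oracle(seed):
    scenario = random_small_scenario(seed)
    needs = estimate_all_needs(scenario)
    exp_enc = oracle.encounters(scenario, oracle.need_by_country(scenario))
    exp_fte = oracle.ftes(scenario, exp_enc)
    for est in estimate_all_workforce(scenario, needs):
        exp = exp_enc[est.country]
        assert est.inpatient_days == pytest.approx(exp["inpatient"], rel=1e-9, abs=1e-9)
        assert est.outpatient_visits == pytest.approx(exp["outpatient"], rel=1e-9, abs=1e-9)
        assert est.home_visits == pytest.approx(exp["home"], rel=1e-9, abs=1e-9)
        for cat, total in exp_fte[est.country].items():
            assert est.fte_total(cat) == pytest.approx(total, rel=1e-9, abs=1e-12)


def test_fte_total_is_sum_over_levels(default_scenario):
    needs = estimate_all_needs(default_scenario)
    for est in estimate_all_workforce(default_scenario, needs)[:3]:
        for cat, by_level in est.fte_by_level.items():
            assert est.fte_total(cat) == pytest.approx(sum(by_level.values()),
                                                       rel=1e-12)


def test_fte_linearity_in_patient_counts():
    rows = [EncounterCoefficient(condition="neoplasms", status="decedent",
                                 level=CareLevel.referral_hospital,
                                 inpatient_days_per_patient=3.0)]
    norms = [StaffingNorm(staff_category="doctor", level=CareLevel.referral_hospital,
                          hours_per_inpatient_day=0.5, annual_fte_hours=1650.0)]
    def doctor_fte(n):
        inp, outp, home = encounter_totals(_need(n), rows)
        return staff_fte(inp, outp, home, norms)["doctor"]["referral_hospital"]
    assert doctor_fte(500.0) == pytest.approx(5 * doctor_fte(100.0), rel=1e-12)
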