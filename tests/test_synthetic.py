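"""Generator: determinism, planted structure, documented coefficient cells."""

import pytest

from palcare import GeneratorSpec, make_scenario, simulate_mortality
from palcare.errors import ScenarioValidationError
from palcare.need import estimate_all_needs
from palcare.opioids import estimate_all_access
from palcare.synthetic import make_default_coefficients, make_default_conditions

from .conftest import SMALL_N_COUNTRIES


def _lookup(rows, condition, symptom, status):
    for r in rows:
        if (r.condition, r.symptom, r.status) == (condition, symptom, status):
            return r
    raise KeyError((condition, symptom, status))


class TestDefaultCoefficients:
    ROWS = make_default_coefficients()

    def test_covers_full_grid(self):
        assert len(self.ROWS) == 20 * 15 * 2

    def test_cancer_decedent_pain_cell(self):
        row = _lookup(self.ROWS, "neoplasms", "pain", "decedent")
        assert (row.prevalence, row.duration_days) == (0.80, 90.0)
        assert row.source == "reported"

    @pytest.mark.parametrize("condition,prevalence", [
        ("lung", 1.00), ("cihd", 0.775), ("nihd", 0.775),
        ("hiv", 0.70), ("liver", 0.50), ("prematurity", 0.50),
    ])
    def test_terminal_dyspnea_prevalences(self, condition, prevalence):
        row = _lookup(self.ROWS, condition, "dyspnea", "decedent")
        assert row.prevalence == prevalence
        assert row.source == "reported"

    def test_all_cells_within_schema_bounds(self):
        assert all(0.0 <= r.prevalence <= 1.0 and r.duration_days >= 0.0
                   for r in self.ROWS)

    def test_placeholder_cells_flagged_assumed(self):
        assumed = [r for r in self.ROWS if r.source == "assumed"]
        assert len(assumed) == len(self.ROWS) - 8


class TestMortality:
    def test_deterministic_under_seed(self):
        spec = GeneratorSpec(seed=1)
        assert simulate_mortality(spec) == simulate_mortality(spec)

    def test_seeds_differ(self):
        assert simulate_mortality(GeneratorSpec(seed=1)) != simulate_mortality(
            GeneratorSpec(seed=2))

    def test_population_scaling_doubles_deaths_within_rounding(self):
        base = simulate_mortality(GeneratorSpec(seed=3))
        doubled = simulate_mortality(GeneratorSpec(seed=3, population_scale=2.0))
        for a, b in zip(base, doubled):
            assert b.population == pytest.approx(2 * a.population, abs=1)
            for code, deaths in a.decedent_deaths.items():
                assert b.decedent_deaths[code] == pytest.approx(2 * deaths, abs=2)

    def test_hiv_dominated_country_present(self):
        recs = simulate_mortality(GeneratorSpec(seed=4, hiv_dominated_country=True))
        lic1 = next(r for r in recs if r.country == "LIC-1")
        hiv = lic1.decedent_deaths["hiv"]
        assert all(hiv >= d for c, d in lic1.decedent_deaths.items() if c != "hiv")

    def test_no_data_country_optional(self):
        recs = simulate_mortality(GeneratorSpec(seed=1, include_no_data_country=True))
        assert sum(not r.data_available for r in recs) == 1


class TestOpioidSupply:
    def _pipeline(self, spec):
        scenario = make_scenario(spec)
        needs = estimate_all_needs(scenario)
        return scenario, needs

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_planted_fraction_recovered(self, fraction):
        spec = GeneratorSpec(seed=5, n_countries=dict(SMALL_N_COUNTRIES),
                             supply_targets={g: fraction for g in SMALL_N_COUNTRIES})
        scenario, needs = self._pipeline(spec)
        for access in estimate_all_access(scenario, needs):
            assert access.percent_met == pytest.approx(100.0 * fraction, abs=1e-9)

    def test_zero_fraction_zero_nonmethadone_supply(self):
        spec = GeneratorSpec(seed=5, n_countries=dict(SMALL_N_COUNTRIES),
                             supply_targets={g: 0.0 for g in SMALL_N_COUNTRIES})
        scenario, _ = self._pipeline(spec)
        non_methadone = [r for r in scenario.opioid_supply if r.opioid != "methadone"]
        assert all(r.quantity_mg == 0.0 for r in non_methadone)
        assert any(r.opioid == "methadone" and r.quantity_mg > 0
                   for r in scenario.opioid_supply)

    def test_decompositions_vary_with_seed_but_totals_planted(self):
        needs_by_seed = {}
        for seed in (1, 2):
            spec = GeneratorSpec(seed=seed, n_countries=dict(SMALL_N_COUNTRIES))
            scenario, needs = self._pipeline(spec)
            needs_by_seed[seed] = scenario
        s1, s2 = needs_by_seed[1], needs_by_seed[2]
        # same planted structure, different random decompositions
        assert [r.quantity_mg for r in s1.opioid_supply] != [
            r.quantity_mg for r in s2.opioid_supply]

    def test_supply_includes_methadone_and_three_products(self):
        scenario = make_scenario(GeneratorSpec(
            seed=6, n_countries=dict(SMALL_N_COUNTRIES)))
        per_country: dict[str, set] = {}
        for r in scenario.opioid_supply:
            per_country.setdefault(r.country, set()).add(r.opioid)
        for products in per_country.values():
            assert "methadone" in products
            assert len(products - {"methadone"}) >= 3


class TestMakeScenario:
    def test_default_shape(self, default_scenario):
        assert len(default_scenario.countries) == 21
        assert len(default_scenario.conditions) == 20
        assert len({r.symptom for r in default_scenario.symptom_coefficients}) == 15

    def test_determinism(self):
        spec = GeneratorSpec(seed=9, n_countries=dict(SMALL_N_COUNTRIES))
        assert make_scenario(spec) == make_scenario(spec)

    def test_invalid_spec_negative_weight_raises(self):
        with pytest.raises((ScenarioValidationError, ValueError)):
            GeneratorSpec(seed=1, condition_weights={"low": {"hiv": -1.0}})

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_scenarios_always_validate(self, seed):
        scenario = make_scenario(GeneratorSpec(
            seed=seed, n_countries=dict(SMALL_N_COUNTRIES)))
        assert scenario.validate() is scenario

    def test_planted_need_fractions_recovered_exactly(self):
        scenario = make_scenario(GeneratorSpec(
            seed=11, n_countries=dict(SMALL_N_COUNTRIES)))
        fractions = {c.code: c.decedent_need_fraction for c in scenario.conditions}
        for est in estimate_all_needs(scenario):
            deaths = scenario.country(est.country).decedent_deaths
            for code, in_need in est.decedents_in_need.items():
                assert in_need == deaths[code] * fractions[code]  # exact

    def test_need_fraction_defaults_match_conditions(self):
        conditions = make_default_conditions()
        assert len(conditions) == 20
        assert all(0 <= c.nondecedent_need_fraction <= c.decedent_need_fraction <= 1
                   for c in conditions)
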