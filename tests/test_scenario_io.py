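"""Scenario directory round-trips, validation errors, report tables."""

import pandas as pd
import pytest

from palcare import (
    GeneratorSpec,
    estimate_all_needs,
    load_scenario,
    make_scenario,
    write_country_table,
    write_scenario,
    write_workforce_table,
)
from palcare.errors import ScenarioIOError, ScenarioValidationError
from palcare.types import NeedEstimate, SymptomBurden
from palcare.workforce import estimate_all_workforce


@pytest.fixture(scope="module")
def scenario_dir(tmp_path_factory):
    scenario = make_scenario(GeneratorSpec(seed=7, include_no_data_country=True))
    root = tmp_path_factory.mktemp("scenario")
    write_scenario(scenario, root)
    return scenario, root


class TestRoundTrip:
    def test_write_then_load_is_identity(self, scenario_dir):
        scenario, root = scenario_dir
        assert load_scenario(root) == scenario

    def test_load_accepts_config_file_path(self, scenario_dir):
        scenario, root = scenario_dir
        assert load_scenario(root / "scenario.yaml") == scenario

    def test_demo_scenario_shape(self, scenario_dir):
        scenario, root = scenario_dir
        loaded = load_scenario(root)
        assert len([c for c in loaded.countries if c.data_available]) == 21
        assert len(loaded.conditions) == 20


class TestValidation:
    def test_missing_directory_is_io_error(self, tmp_path):
        with pytest.raises(ScenarioIOError):
            load_scenario(tmp_path / "nope")

    def test_missing_table_is_io_error(self, scenario_dir, tmp_path):
        _, root = scenario_dir
        broken = tmp_path / "broken"
        broken.mkdir()
        (broken / "scenario.yaml").write_text((root / "scenario.yaml").read_text())
        with pytest.raises(ScenarioIOError, match="conditions"):
            load_scenario(broken)

    def test_out_of_bounds_prevalence_names_row(self, scenario_dir, tmp_path):
        _, root = scenario_dir
        copy = tmp_path / "bad"
        copy.mkdir()
        for f in root.iterdir():
            (copy / f.name).write_text(f.read_text())
        df = pd.read_csv(copy / "symptom_coefficients.csv")
        df.loc[5, "prevalence"] = 1.2
        df.to_csv(copy / "symptom_coefficients.csv", index=False)
        with pytest.raises(ScenarioValidationError) as exc:
            load_scenario(copy)
        assert exc.value.table == "symptom_coefficients.csv"
        assert exc.value.row == 5
        assert exc.value.field == "prevalence"

    def test_dangling_condition_reference_rejected(self, scenario_dir, tmp_path):
        _, root = scenario_dir
        copy = tmp_path / "dangling"
        copy.mkdir()
        for f in root.iterdir():
            (copy / f.name).write_text(f.read_text())
        df = pd.read_csv(copy / "conditions.csv")
        df = df[df.code != "hiv"]
        df.to_csv(copy / "conditions.csv", index=False)
        with pytest.raises((ScenarioValidationError, ScenarioIOError)):
            load_scenario(copy)

    def test_duplicate_condition_codes_rejected(self, scenario_dir, tmp_path):
        _, root = scenario_dir
        copy = tmp_path / "dupes"
        copy.mkdir()
        for f in root.iterdir():
            (copy / f.name).write_text(f.read_text())
        df = pd.read_csv(copy / "conditions.csv")
        pd.concat([df, df.iloc[[0]]]).to_csv(copy / "conditions.csv", index=False)
        with pytest.raises(ScenarioValidationError, match="duplicate"):
            load_scenario(copy)


def _toy_rows(country="Afghanistan", dec=95_000.0, nondec=71_000.0,
              at_most=40e6, at_least=13e6):
    need = NeedEstimate(country=country, decedents_in_need={"neoplasms": dec},
                        nondecedents_in_need={"neoplasms": nondec})
    burden = SymptomBurden(country=country, at_least_days=at_least,
                           at_most_days=at_most,
                           per_symptom_days={"pain": at_most})
    return need, burden


class TestCountryTable:
    def test_published_style_row_in_thousands(self, tmp_path):
        need, burden = _toy_rows()
        frame = write_country_table([need], [burden], tmp_path / "t1.csv")
        row = frame.iloc[0]
        assert (row["decedents_thousands"], row["nondecedents_thousands"],
                row["total_thousands"]) == ("95", "71", "166")
        assert row["at_most_symptom_days_millions"] == "40"
        assert row["at_least_symptom_days_millions"] == "13"

    def test_empty_input_header_only(self, tmp_path):
        frame = write_country_table([], [], tmp_path / "t1.csv")
        assert frame.empty
        assert (tmp_path / "t1.csv").read_text().count("\n") == 1

    def test_total_row_from_unrounded_values(self, tmp_path):
        # two countries at x499.6 thousand: rounded rows print 500 each,
        # but the Total must come from the unrounded sum (999.2 -> 999)
        n1, b1 = _toy_rows("A", dec=499_600.0, nondec=0.0)
        n2, b2 = _toy_rows("B", dec=499_600.0, nondec=0.0)
        frame = write_country_table([n1, n2], [b1, b2], tmp_path / "t1.csv")
        total = frame[frame.country == "Total"].iloc[0]
        assert frame.iloc[0]["decedents_thousands"] == "500"
        assert total["decedents_thousands"] == "999"

    def test_mismatched_country_sets_rejected(self, tmp_path):
        n1, b1 = _toy_rows("A")
        _, b2 = _toy_rows("B")
        with pytest.raises(ScenarioValidationError):
            write_country_table([n1], [b2], tmp_path / "t1.csv")

    def test_no_data_country_printed_but_excluded_from_total(self, tmp_path):
        need, burden = _toy_rows("A", dec=1000.0, nondec=0.0)
        frame = write_country_table([need], [burden], tmp_path / "t1.csv",
                                    no_data=[("Palestine", "low")])
        nd = frame[frame.country == "Palestine"].iloc[0]
        assert nd["decedents_thousands"] == "No data"
        total = frame[frame.country == "Total"].iloc[0]
        assert total["decedents_thousands"] == "1"

    def test_grouped_by_income_group(self, tmp_path):
        rows = [_toy_rows(c) for c in ("H1", "L1", "M1")]
        groups = {"H1": "high", "L1": "low", "M1": "upper-middle"}
        frame = write_country_table([r[0] for r in rows], [r[1] for r in rows],
                                    tmp_path / "t1.csv", income_groups=groups)
        assert list(frame.country[:3]) == ["L1", "M1", "H1"]


class TestWorkforceTable:
    def test_per_100k_cells_two_decimals(self, tmp_path, default_scenario):
        needs = estimate_all_needs(default_scenario)
        estimates = estimate_all_workforce(default_scenario, needs)
        frame = write_workforce_table(estimates, tmp_path / "t2.csv")
        for _, row in frame.iterrows():
            for cat in ("doctor", "nurse", "community_health_worker"):
                cell = row[f"fte_per_100k_{cat}"]
                whole, frac = str(cell).split(".")
                assert len(frac) == 2

    def test_zero_fte_prints_zero_cells(self, tmp_path):
        from .test_workforce import _estimate_with_fte

        est = _estimate_with_fte("A", 1_000_000, {})
        frame = write_workforce_table([est], tmp_path / "t2.csv")
        assert frame.iloc[0]["fte_per_100k_doctor"] == "0.00"
        assert frame.iloc[0]["fte_doctor"] == "0"

    def test_empty_estimates_rejected(self, tmp_path):
        with pytest.raises(ScenarioValidationError):
            write_workforce_table([], tmp_path / "t2.csv")

    def test_cells_match_hand_recomputation(self, tmp_path):
        spec = GeneratorSpec(seed=2, n_countries={"low": 1, "lower-middle": 1,
                                                  "upper-middle": 1, "high": 0})
        scenario = make_scenario(spec)
        needs = estimate_all_needs(scenario)
        estimates = estimate_all_workforce(scenario, needs)
        frame = write_workforce_table(estimates, tmp_path / "t2.csv")
        from palcare.rounding import fmt_half_up

        from . import oracle

        exp_enc = oracle.encounters(scenario, oracle.need_by_country(scenario))
        exp_fte = oracle.ftes(scenario, exp_enc)
        for est, (_, row) in zip(estimates, frame.iterrows()):
            enc = exp_enc[est.country]
            assert row["home_visits"] == fmt_half_up(enc["home"], 0)
            assert row["referral_hospital_inpatient_days"] == fmt_half_up(
                enc["inpatient"]["referral_hospital"], 0)
            for cat, total in exp_fte[est.country].items():
                assert row[f"fte_{cat}"] == fmt_half_up(total, 0)
                assert row[f"fte_per_100k_{cat}"] == fmt_half_up(
                    100_000.0 * total / est.population, 2)
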