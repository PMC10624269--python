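"""Scenario directory I/O and report-table writers.

A scenario lives in one directory of plain CSV tables plus a
``scenario.yaml`` config declaring the table filenames, the reference
year, and the model options.  The layout is deliberately inspectable:
every coefficient a run uses can be diffed and audited as text.

Rounding conventions for report tables (applied only here, never inside
the pipeline): counts of people in thousands and symptom days in
millions are rounded half-up to integers, FTE counts to integers, FTE
per 100,000 to two decimals.  Total rows are computed from unrounded
country values and rounded last.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import ValidationError

from .errors import ScenarioIOError, ScenarioValidationError
from .rounding import fmt_half_up
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
    SymptomBurden,
    SymptomCoefficient,
    WorkforceEstimate,
)
from .vocab import FACILITY_LEVELS, INCOME_GROUPS, STAFF_CATEGORIES

__all__ = [
    "load_scenario", "write_scenario",
    "write_country_table", "write_workforce_table",
]

SCHEMA_VERSION = 1
CONFIG_NAME = "scenario.yaml"

_DEFAULT_TABLES = {
    "countries": "countries.csv",
    "conditions": "conditions.csv",
    "symptom_coefficients": "symptom_coefficients.csv",
    "opioid_supply": "opioid_supply.csv",
    "equianalgesic": "equianalgesic.csv",
    "encounter_coefficients": "encounter_coefficients.csv",
    "staffing_norms": "staffing_norms.csv",
    "level_allocation": "level_allocation.csv",
}


def _read_csv(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise ScenarioIOError(f"missing scenario table {table!r}: {path}")
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ScenarioIOError(f"cannot parse {path}: {exc}") from exc


def _rows(df: pd.DataFrame, model: type, table: str) -> list[Any]:
    """Build one pydantic record per CSV row, naming the row on failure."""
    out = []
    for i, raw in enumerate(df.to_dict(orient="records")):
        data = {k: v for k, v in raw.items() if not pd.isna(v)}
        try:
            out.append(model(**data))
        except ValidationError as exc:
            err = exc.errors()[0]
            field = ".".join(str(p) for p in err["loc"]) or None
            raise ScenarioValidationError(
                err["msg"], table=table, row=i, field=field) from exc
    return out


def _countries_from_frame(df: pd.DataFrame, codes: Sequence[str],
                          table: str) -> list[CountryRecord]:
    records = []
    for i, raw in enumerate(df.to_dict(orient="records")):
        available = bool(raw.get("data_available", True))
        deaths = {}
        cases = {}
        for code in codes:
            v = raw.get(f"deaths_{code}")
            if v is not None and not pd.isna(v):
                deaths[code] = float(v)
            v = raw.get(f"cases_{code}")
            if v is not None and not pd.isna(v):
                cases[code] = float(v)
        population = raw.get("population")
        try:
            records.append(CountryRecord(
                country=raw["country"],
                income_group=raw["income_group"],
                population=None if pd.isna(population) else int(population),
                decedent_deaths=deaths if available else {},
                nondecedent_cases=cases if available else {},
                data_available=available,
            ))
        except (ValidationError, ValueError, KeyError) as exc:
            msg = exc.errors()[0]["msg"] if isinstance(exc, ValidationError) else str(exc)
            raise ScenarioValidationError(msg, table=table, row=i) from exc
    return records


def load_scenario(path: str | Path) -> Scenario:
    """Load and fully validate a scenario directory (or its config file).

    Raises
    ------
    ScenarioIOError
        If the config or a declared table is missing or unparseable.
    ScenarioValidationError
        If any record violates a field bound or cross-table invariant;
        the error names the table, row and field where possible.
    """
    path = Path(path)
    config_path = path / CONFIG_NAME if path.is_dir() else path
    if not config_path.exists():
        raise ScenarioIOError(f"scenario config not found: {config_path}")
    root = config_path.parent
    try:
        config = yaml.safe_load(config_path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioIOError(f"cannot parse {config_path}: {exc}") from exc
    if not isinstance(config, dict):
        raise ScenarioValidationError(f"config {config_path} is not a mapping")
    version = config.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ScenarioValidationError(
            f"unsupported schema_version {version!r}, expected {SCHEMA_VERSION}")

    tables = {**_DEFAULT_TABLES, **(config.get("tables") or {})}

    conditions = _rows(_read_csv(root / tables["conditions"], "conditions.csv"),
                       Condition, "conditions.csv")
    codes = [c.code for c in conditions]
    countries = _countries_from_frame(
        _read_csv(root / tables["countries"], "countries.csv"), codes, "countries.csv")
    coeffs = _rows(_read_csv(root / tables["symptom_coefficients"],
                             "symptom_coefficients.csv"),
                   SymptomCoefficient, "symptom_coefficients.csv")

    def optional(name: str, model: type) -> list[Any]:
        p = root / tables[name]
        if not p.exists():
            return []
        return _rows(_read_csv(p, tables[name]), model, tables[name])

    try:
        options = ModelOptions(**(config.get("options") or {}))
        requirement = RequirementParams(**(config.get("requirement") or {}))
    except ValidationError as exc:
        err = exc.errors()[0]
        raise ScenarioValidationError(err["msg"], table=CONFIG_NAME,
                                      field=".".join(map(str, err["loc"]))) from exc

    scenario = Scenario(
        reference_year=int(config.get("reference_year", 2015)),
        conditions=conditions,
        countries=countries,
        symptom_coefficients=coeffs,
        opioid_supply=optional("opioid_supply", OpioidSupplyRecord),
        equianalgesic_table=optional("equianalgesic", EquianalgesicFactor),
        requirement_params=requirement,
        encounter_coefficients=optional("encounter_coefficients", EncounterCoefficient),
        staffing_norms=optional("staffing_norms", StaffingNorm),
        level_allocation=optional("level_allocation", LevelAllocation),
        options=options,
    )
    return scenario.validate()


def _exact_floats(frame: pd.DataFrame) -> pd.DataFrame:
    """Render floats as shortest round-trip reprs so write/read is exact."""
    return frame.map(lambda v: repr(v) if isinstance(v, float) and not pd.isna(v) else v)


def write_scenario(scenario: Scenario, path: str | Path) -> Path:
    """Write a scenario as a directory of CSV tables plus scenario.yaml.

    ``write_scenario`` then :func:`load_scenario` reproduces the scenario
    field-by-field.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    codes = scenario.condition_codes

    _exact_floats(pd.DataFrame([c.model_dump() for c in scenario.conditions])).to_csv(
        root / "conditions.csv", index=False)

    rows = []
    for rec in scenario.countries:
        row: dict[str, Any] = {
            "country": rec.country,
            "income_group": rec.income_group,
            "population": rec.population,
            "data_available": rec.data_available,
        }
        for code in codes:
            row[f"deaths_{code}"] = rec.decedent_deaths.get(code) if rec.data_available else None
            row[f"cases_{code}"] = rec.nondecedent_cases.get(code) if rec.data_available else None
        rows.append(row)
    _exact_floats(pd.DataFrame(rows)).to_csv(root / "countries.csv", index=False)

    def dump(records: Sequence[Any], name: str) -> None:
        frame = pd.DataFrame([r.model_dump() for r in records])
        if "level" in frame.columns:
            frame["level"] = [r.level.value for r in records]
        _exact_floats(frame).to_csv(root / name, index=False)

    dump(scenario.symptom_coefficients, "symptom_coefficients.csv")
    if scenario.opioid_supply:
        dump(scenario.opioid_supply, "opioid_supply.csv")
    if scenario.equianalgesic_table:
        dump(scenario.equianalgesic_table, "equianalgesic.csv")
    if scenario.encounter_coefficients:
        dump(scenario.encounter_coefficients, "encounter_coefficients.csv")
    if scenario.staffing_norms:
        dump(scenario.staffing_norms, "staffing_norms.csv")
    if scenario.level_allocation:
        dump(scenario.level_allocation, "level_allocation.csv")

    config = {
        "schema_version": SCHEMA_VERSION,
        "reference_year": scenario.reference_year,
        "tables": dict(_DEFAULT_TABLES),
        "options": scenario.options.model_dump(),
        "requirement": scenario.requirement_params.model_dump(),
    }
    (root / CONFIG_NAME).write_text(yaml.safe_dump(config, sort_keys=False))
    return root


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def write_country_table(needs: Sequence[NeedEstimate],
                        burdens: Sequence[SymptomBurden],
                        path: str | Path,
                        *,
                        income_groups: Mapping[str, str] | None = None,
                        no_data: Sequence[tuple[str, str]] = ()) -> pd.DataFrame:
    """Write the per-country need and symptom-day summary table.

    One row per country (grouped by income group when ``income_groups``
    is given) plus a Total row computed from unrounded values; countries
    listed in ``no_data`` appear with "No data" cells and contribute
    nothing to the Total.
    """
    need_countries = [n.country for n in needs]
    burden_by_country = {b.country: b for b in burdens}
    if set(need_countries) != set(burden_by_country):
        raise ScenarioValidationError(
            "need and burden estimates cover different country sets: "
            f"{sorted(set(need_countries) ^ set(burden_by_country))}")

    groups = income_groups or {}
    order = sorted(
        range(len(needs)),
        key=lambda i: INCOME_GROUPS.index(groups[need_countries[i]])
        if need_countries[i] in groups else len(INCOME_GROUPS),
    )

    rows = []
    for i in order:
        est, burden = needs[i], burden_by_country[need_countries[i]]
        rows.append({
            "country": est.country,
            "income_group": groups.get(est.country, ""),
            "at_most_symptom_days_millions": fmt_half_up(burden.at_most_days / 1e6, 0),
            "at_least_symptom_days_millions": fmt_half_up(burden.at_least_days / 1e6, 0),
            "decedents_thousands": fmt_half_up(est.decedent_total / 1e3, 0),
            "nondecedents_thousands": fmt_half_up(est.nondecedent_total / 1e3, 0),
            "total_thousands": fmt_half_up(est.grand_total / 1e3, 0),
        })
    for country, group in no_data:
        rows.append({"country": country, "income_group": group,
                     **{col: "No data" for col in (
                         "at_most_symptom_days_millions",
                         "at_least_symptom_days_millions",
                         "decedents_thousands", "nondecedents_thousands",
                         "total_thousands")}})
    if needs:
        rows.append({
            "country": "Total",
            "income_group": "",
            "at_most_symptom_days_millions":
                fmt_half_up(sum(b.at_most_days for b in burdens) / 1e6, 0),
            "at_least_symptom_days_millions":
                fmt_half_up(sum(b.at_least_days for b in burdens) / 1e6, 0),
            "decedents_thousands":
                fmt_half_up(sum(n.decedent_total for n in needs) / 1e3, 0),
            "nondecedents_thousands":
                fmt_half_up(sum(n.nondecedent_total for n in needs) / 1e3, 0),
            "total_thousands":
                fmt_half_up(sum(n.grand_total for n in needs) / 1e3, 0),
        })
    columns = ["country", "income_group",
               "at_most_symptom_days_millions", "at_least_symptom_days_millions",
               "decedents_thousands", "nondecedents_thousands", "total_thousands"]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)
    return frame


def write_workforce_table(estimates: Sequence[WorkforceEstimate],
                          path: str | Path) -> pd.DataFrame:
    """Write the per-country encounter and staffing requirement table.

    Patient counts and encounter volumes are rounded to integers, FTEs to
    integers, FTEs per 100,000 to two decimals — all half-up, all from
    unrounded internal values.
    """
    if not estimates:
        raise ScenarioValidationError("write_workforce_table requires estimates")
    rows = []
    for est in estimates:
        row: dict[str, Any] = {
            "country": est.country,
            "population": est.population,
            "decedents": fmt_half_up(est.decedents, 0),
            "nondecedents": fmt_half_up(est.nondecedents, 0),
            "total_patients": fmt_half_up(est.total_patients, 0),
        }
        for level in FACILITY_LEVELS:
            row[f"{level}_inpatient_days"] = fmt_half_up(est.inpatient_days[level], 0)
            row[f"{level}_outpatient_visits"] = fmt_half_up(est.outpatient_visits[level], 0)
        row["home_visits"] = fmt_half_up(est.home_visits, 0)
        for cat in STAFF_CATEGORIES:
            row[f"fte_{cat}"] = fmt_half_up(est.fte_total(cat), 0)
        for cat in STAFF_CATEGORIES:
            row[f"fte_per_100k_{cat}"] = fmt_half_up(est.fte_per_100k(cat), 2)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
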