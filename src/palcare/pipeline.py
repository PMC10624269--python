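"""End-to-end pipeline orchestration and figure-data export.

``run_pipeline`` sequences the four estimation stages — need, symptom
burden, opioid access, workforce — over a validated scenario, persists
every stage result as CSV (so each stage is independently auditable),
and writes a run manifest.  Every output is a pure function of the
scenario, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import MissingStageError, ScenarioValidationError
from .need import condition_shares, estimate_all_needs
from .opioids import estimate_all_access
from .scenario_io import write_country_table, write_workforce_table
from .symptoms import estimate_all_burdens, symptom_shares
from .types import (
    NeedEstimate,
    OpioidAccess,
    Scenario,
    SymptomBurden,
    WorkforceEstimate,
)
from .workforce import estimate_all_workforce

__all__ = ["STAGES", "PipelineResult", "RunManifest", "run_pipeline",
           "export_figure_data"]

STAGES = ("need", "symptoms", "opioids", "workforce")


@dataclasses.dataclass
class PipelineResult:
    """In-memory results of a pipeline run; stages not run are None."""

    scenario: Scenario
    needs: list[NeedEstimate] | None = None
    burdens: list[SymptomBurden] | None = None
    access: list[OpioidAccess] | None = None
    workforce: list[WorkforceEstimate] | None = None


@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every run's outputs."""

    scenario_path: str
    seed: int | None
    stages: list[str]
    outputs: list[str]
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _scenario_hash(scenario: Scenario, seed: int | None) -> str:
    payload = json.dumps(
        {"scenario": scenario.model_dump(mode="json"), "seed": seed},
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def compute_stages(scenario: Scenario, skip: tuple[str, ...] = ()) -> PipelineResult:
    """Run the estimation stages in memory, honouring ``skip``.

    Symptoms, opioids and workforce all consume the need stage, so
    skipping ``need`` skips everything downstream.
    """
    for stage in skip:
        if stage not in STAGES:
            raise ScenarioValidationError(f"unknown stage {stage!r}")
    result = PipelineResult(scenario=scenario)
    if "need" in skip:
        return result
    result.needs = estimate_all_needs(scenario)
    if "symptoms" not in skip:
        result.burdens = estimate_all_burdens(scenario, result.needs)
    if "opioids" not in skip:
        result.access = estimate_all_access(scenario, result.needs)
    if "workforce" not in skip:
        result.workforce = estimate_all_workforce(scenario, result.needs)
    return result


def export_figure_data(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the three figure datasets in long format (country, key, value).

    fig1: per-condition percentage shares of need; fig2: per-symptom
    percentage shares of at-most symptom days; fig3: DOME per patient and
    percent of opioid need met.  Raises
    :class:`~palcare.errors.MissingStageError` if the backing stage did
    not run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if result.needs is None:
        raise MissingStageError("need stage did not run; no figure data to export")
    rows = [
        {"country": est.country, "key": code, "value": share}
        for est in result.needs
        for code, share in condition_shares(est).items()
    ]
    path = out_dir / "fig1_condition_shares.csv"
    pd.DataFrame(rows, columns=["country", "key", "value"]).to_csv(path, index=False)
    written.append(path)

    if result.burdens is not None:
        rows = [
            {"country": b.country, "key": symptom, "value": share}
            for b in result.burdens
            for symptom, share in symptom_shares(b).items()
        ]
        path = out_dir / "fig2_symptom_shares.csv"
        pd.DataFrame(rows, columns=["country", "key", "value"]).to_csv(path, index=False)
        written.append(path)

    if result.access is not None:
        rows = []
        for a in result.access:
            rows.append({"country": a.country, "key": "dome_per_patient_mg",
                         "value": a.dome_per_patient_mg})
            rows.append({"country": a.country, "key": "percent_met",
                         "value": a.percent_met})
        path = out_dir / "fig3_opioid_access.csv"
        pd.DataFrame(rows, columns=["country", "key", "value"]).to_csv(path, index=False)
        written.append(path)
    return written


def run_pipeline(scenario: Scenario, out_dir: str | Path, *,
                 skip: tuple[str, ...] = (), seed: int | None = None,
                 scenario_path: str = "<in-memory>") -> tuple[PipelineResult, RunManifest]:
    """Run all stages and write every output table plus a manifest.

    Writes per-stage CSV intermediates, the two report tables and the
    three figure datasets under ``out_dir``.  Outputs are deterministic:
    the same scenario produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = compute_stages(scenario, skip)
    outputs: list[str] = []
    groups = {c.country: c.income_group for c in scenario.countries}
    no_data = [(c.country, c.income_group) for c in scenario.countries
               if not c.data_available]

    if result.needs is not None:
        rows = [
            {"country": est.country, "condition": code, "status": status,
             "in_need": est.in_need(code, status)}
            for est in result.needs
            for code in scenario.condition_codes
            for status in ("decedent", "nondecedent")
        ]
        pd.DataFrame(rows).to_csv(out_dir / "needs.csv", index=False)
        outputs.append("needs.csv")

    if result.burdens is not None:
        rows = [
            {"country": b.country, "at_least_days": b.at_least_days,
             "at_most_days": b.at_most_days}
            for b in result.burdens
        ]
        pd.DataFrame(rows).to_csv(out_dir / "symptom_burden.csv", index=False)
        outputs.append("symptom_burden.csv")
        write_country_table(result.needs, result.burdens, out_dir / "table1.csv",
                            income_groups=groups, no_data=no_data)
        outputs.append("table1.csv")

    if result.access is not None:
        rows = [a.model_dump() for a in result.access]
        pd.DataFrame(rows).to_csv(out_dir / "opioid_access.csv", index=False)
        outputs.append("opioid_access.csv")

    if result.workforce is not None:
        write_workforce_table(result.workforce, out_dir / "table2.csv")
        outputs.append("table2.csv")

    if result.needs is not None:
        outputs.extend(p.name for p in export_figure_data(result, out_dir))

    manifest = RunManifest(
        scenario_path=str(scenario_path),
        seed=seed,
        stages=[s for s in STAGES if s not in skip],
        outputs=sorted(outputs),
        config_hash=_scenario_hash(scenario, seed),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return result, manifest
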