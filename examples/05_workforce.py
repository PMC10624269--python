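"""Workforce requirements: encounter-days, FTEs, and per-100k bands.

Patients in need generate inpatient days, outpatient visits and home
visits at five care levels; staffing norms (staff-hours per encounter
unit / annual FTE hours) convert those to full-time equivalents.
"""

from palcare import (
    GeneratorSpec,
    estimate_all_needs,
    estimate_all_workforce,
    make_scenario,
    workforce_summary_range,
)

scenario = make_scenario(GeneratorSpec(seed=7))
needs = estimate_all_needs(scenario)
estimates = estimate_all_workforce(scenario, needs)

est = estimates[0]
print(f"{est.country}: {est.total_patients:,.0f} patients in need")
print(f"  home visits/year:        {est.home_visits:,.0f}")
print(f"  doctor FTEs:             {est.fte_total('doctor'):,.1f} "
      f"({est.fte_per_100k('doctor'):.2f} per 100k)")
print(f"  nurse FTEs:              {est.fte_total('nurse'):,.1f} "
      f"({est.fte_per_100k('nurse'):.2f} per 100k)")
print(f"  community health workers: {est.fte_total('community_health_worker'):,.1f} "
      f"({est.fte_per_100k('community_health_worker'):.2f} per 100k)")

lo, hi = workforce_summary_range(estimates, "community_health_worker")
print(f"CHW FTEs per 100k across the region: {lo} to {hi}")
print("CHWs dominate because safe home care needs frequent home visits;")
print("per-100k values let planners compare staffing needs across countries.")
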