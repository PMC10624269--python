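# palcare

Needs-based palliative care planning: from mortality and prevalence
envelopes to people in need, symptom-day burden bounds, opioid access
metrics, and health-workforce requirements.

## The problem

Most people who need palliative care — the prevention and relief of
suffering associated with serious illness — never receive it, and
health ministries rarely have the numbers needed to plan services:
how many people need care, what kinds of suffering dominate, whether
opioid analgesics are accessible, and how many staff of which kinds a
universally accessible essential package would take. `palcare`
implements that estimation chain as a reusable, tested library for
health planners and researchers working with country-level data.

## The model

For each of 20 serious-illness conditions *c* and each country, with
*N* deaths (decedents) or prevalent non-fatal cases (non-decedents) and
need fractions *f*:

* **Need**: `in_need(c) = N(c) · f(c)`, summed over conditions and
  statuses; condition shares say which illnesses generate the need.
* **Symptom-day bounds**: with prevalence *p* and duration *d* per
  (condition, symptom, status), the burden of suffering lies between
  `at_least = Σ N·p·d` over only the longest-duration symptom per cell
  and `at_most = Σ N·p·d` over all symptoms.
* **Opioid access**: DOME (distributed-opioid oral morphine
  equivalents) converts non-methadone opioid supplies to oral morphine
  mg via an equianalgesic table; the modelled requirement doses
  moderate/severe pain (67.5 mg/day) and refractory terminal dyspnea
  (10 mg/day) over their durations; `percent_met = 100·DOME/required`,
  uncapped.
* **Workforce**: patients generate inpatient days, outpatient visits
  and home visits at five care levels; staffing norms (staff-hours per
  encounter / annual FTE hours) convert encounters into FTEs for ten
  staff categories, absolute and per 100,000 population.

A synthetic-scenario generator (`palcare.synthetic`) produces complete,
internally consistent regions — 21 countries in four income groups,
income-specific condition mixes, an HIV-dominated country, opioid
supplies planted at known fractions of need — so the whole pipeline is
testable without any external data. See `docs/methods.md` for the full
model description, defaults and limitations.

## Worked example

```python
from palcare import (GeneratorSpec, make_scenario, estimate_all_needs,
                     estimate_all_workforce, regional_totals,
                     workforce_summary_range)

scenario = make_scenario(GeneratorSpec(seed=7))
needs = estimate_all_needs(scenario)
region = regional_totals(needs)
print(f"region total in need: {region.grand_total:,.0f}")

estimates = estimate_all_workforce(scenario, needs)
lo, hi = workforce_summary_range(estimates, "community_health_worker")
print(f"CHW FTEs per 100k across the region: {lo} to {hi}")
```

prints

```
region total in need: 3,796,968
CHW FTEs per 100k across the region: 4.0 to 7.0
```

— about 3.8 million people in this synthetic region need palliative
care, and making home-centred care universal would take between 4.0 and
7.0 community-health-worker FTEs per 100,000 population depending on
the country. The `examples/` directory
has one short script per capability (generation, need, symptom burden,
opioid access, workforce, published arithmetic), each printing its
numbers with a line on what they mean.

The same pipeline is available as a thin CLI:

```sh
palcare simulate --seed 7 --out scenario/
palcare report --scenario scenario/ --out results/
```

which writes the per-country need/symptom-day table (`table1.csv`), the
workforce table (`table2.csv`), three figure datasets in long format,
and a run manifest; outputs are byte-identical across reruns.

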