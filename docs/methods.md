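# Methods

`palcare` is a deterministic accounting pipeline for needs-based
palliative care planning. It takes a *scenario* — country-level
mortality and prevalence envelopes, condition-level symptom
coefficients, opioid distribution data, and health-system norms — and
produces four families of estimates: people in need of palliative care,
symptom-day burden bounds, opioid access metrics, and workforce
requirements. This note records the model, its assumptions, the
defaults, and the places where the design was genuinely open.

## The need model

The framework rests on a closed list of 20 serious-illness conditions
(the ICD-10 groups that most commonly generate moderate or severe
physical or psychological suffering). For each condition *c* and
country, two populations are distinguished:

* **decedents** — people who died of *c* in the reference year;
* **non-decedents** — people living with *c* who did not die of it that
  year.

Need is linear in the envelopes:

    decedents_in_need(c)    = deaths(c)  x f_dec(c)
    nondecedents_in_need(c) = cases(c)   x f_nondec(c)

where `f_dec`, `f_nondec` ∈ [0, 1] are the per-condition need fractions
(the proportion whose suffering requires palliation). Totals are sums;
fractional persons are carried at full float precision and rounded only
at the reporting boundary (half-up; thousands for people, millions for
symptom-days, two decimals for per-100k rates). Countries flagged as
having no data are printed as "No data" and excluded from every
aggregate — never imputed. Report-table Total rows are computed from
unrounded country values and rounded last, so a column of independently
rounded country cells may differ from the printed Total by one unit;
that is the intended convention.

## Symptom-day bounds

A *symptom-day* is one day on which one person experiences one moderate
or severe symptom. The coefficient table gives, per (condition, symptom,
status ∈ {decedent, non-decedent}), a prevalence *p* and a mean duration
*d* in days. Because co-occurrence of symptoms within calendar days is
unknown, the burden is bracketed rather than estimated:

* **at-most**: Σ over all symptoms of N·p·d — counts each symptom's days
  separately even when they overlap in time;
* **at-least**: per (condition, status) cell, only the symptom of
  longest duration contributes N·p·d — the minimum number of distinct
  suffering days consistent with the table.

Two underdetermined choices are explicit options:

* `at_least_weighting` — the lower bound weights the longest symptom by
  its prevalence (default `"prevalence"`); the alternative `"unit"`
  treats it as universal. Note that the unit option can exceed the
  at-most bound when the longest symptom's prevalence is well below 1;
  the default preserves `at_least ≤ at_most` unconditionally.
* Duration ties are broken by higher prevalence, then lexicographic
  symptom label, so the bound is deterministic.

Per-symptom shares (the figure-2-style output) use the at-most
accounting and sum to 100 per country.

## Opioid access (DOME)

DOME — distributed-opioid oral morphine equivalents — is the quantity of
strong opioids **other than methadone** distributed in a country,
converted to oral morphine milligrams through an equianalgesic table.
Methadone is excluded because its distribution is dominated by
opioid-agonist therapy. Default factors (mg oral morphine per mg
product; all overridable in `equianalgesic.csv`): oral morphine 1, oral
oxycodone 1.5, oral hydromorphone 4, parenteral morphine 3, transdermal
fentanyl 100.

The modelled requirement doses two indications:

    required = Σ_c,m N(c,m) · [ p_pain·d_pain·D_pain  +  p_dysp·d_dysp·D_dysp ]

with default daily doses D_pain = 67.5 mg/day and D_dysp = 10 mg/day
oral morphine equivalent. Both doses are planning assumptions, not
published constants, and live in the scenario config. The pain term
covers decedents and non-decedents by default
(`requirement_population: all`; a `decedents` switch exists because the
published method does not state the choice); the refractory *terminal*
dyspnea term covers decedents only, since "terminal" implies
end-of-life. Percent of need met is 100·DOME/required, deliberately
uncapped — values above 100 mean supply exceeds the modelled palliative
need. A `procedural_fraction` hook subtracts an assumed
surgical/procedural share from DOME for sensitivity analysis; the
default is 0 (no correction), matching the published treatment.

## Workforce model

Patients in need generate encounters at five care levels (referral,
provincial and district hospitals, community health centres, home)
through per-patient encounter coefficients; encounters convert to staff
full-time equivalents through staffing norms:

    FTE(cat, level) = [ inpatient_days(level)·h_ipd + outpatient_visits(level)·h_opv
                        + home_visits·h_hv (home only) ] / annual_fte_hours

for ten staff categories (doctors, nurses, social workers, spiritual
counsellors, psychologists/psychiatrists, physical therapists,
pharmacists, community health workers, clinical support, non-clinical
support). Default annual FTE hours: 1,650, a standard full-time planning
figure. Per-100,000 rates are 100,000·FTE/population, reported to two
decimals; cross-country min–max bands are reported to one decimal.

How care splits across the five levels is a planning choice, not a
published constant, so it is an explicit input: `level_allocation.csv`
holds a share profile per income group (low-income profiles lean toward
home and district care, high-income toward hospitals). Because the
encounter-coefficient table is shared by all countries in a scenario,
the generator blends the group profiles (unweighted mean) when deriving
the default coefficients; users who want group-specific allocations can
generate one scenario per group or supply their own coefficient table.

## The synthetic generator

Real inputs (national cause-of-death extracts, narcotics-board
distribution data, appendix coefficient tables) cannot be redistributed,
so `palcare.synthetic` generates scenarios with the same structure, and
every default is chosen to emulate the study conditions:

* **Region shape**: 21 countries with data in four income groups
  (3 low, 7 lower-middle, 5 upper-middle, 6 high), optionally plus one
  no-data country; reference year 2015.
* **Mortality**: deaths ≈ population x crude death rate (0.7%/yr,
  jittered) x serious-illness share (45% — the share of deaths the 20
  conditions account for) x a per-country condition mix drawn around
  income-group weight profiles. One low-income country gets an
  HIV-dominated mix (HIV need share > 70%) when requested (the default).
* **Non-decedent cases** are generated directly as a jittered
  per-condition multiple (base 2.0) of deaths — not derived from
  incidence and duration, because the framework defines non-decedents
  only as prevalent non-fatal cases.
* **Symptom coefficients**: the full 20 x 15 x 2 grid. Eight cells are
  fixed at explicitly evidence-stated values (cancer-decedent pain 0.80
  prevalence x 90 days; terminal dyspnea 1.00 for chronic lung disease,
  0.775 for both heart-disease groups — the midpoint of the stated
  75–80% range — 0.70 HIV/AIDS, 0.50 liver disease, 0.50
  prematurity/birth trauma) and flagged `source="reported"`. Every other
  cell carries a documented placeholder flagged `"assumed"`, calibrated
  so that the generated region reproduces the qualitative structure the
  evidence describes: pain, fatigue and weakness together carry more
  than half of all symptom-days, and anxiety plus depressed mood about a
  fifth to a quarter. Non-decedent placeholders halve the decedent
  prevalence and keep the duration — an explicit assumption, since
  non-decedent durations are nowhere stated.
* **Opioid supply** is planted: per country, total DOME equals an
  income-group target fraction of the modelled requirement (defaults
  0.005 / 0.05 / 0.5 / 1.2 from low to high income, spanning well under
  1% to above 100% of need), decomposed across three non-methadone
  products by a random Dirichlet draw, plus a methadone quantity the
  conversion must ignore. This makes the generator a closed-loop
  harness: the pipeline must recover percent_need_met = 100·f to 1e-9.
* **Encounter intensities**: base 14 inpatient days, 8 outpatient
  visits, 100 home visits per decedent (4/6/45 per non-decedent), split
  across levels by the blended allocation. The home-visit base is set so
  that a patient in need receives on the order of 30 home visits and
  community health workers come out as the largest staff category —
  the structure a home-care-centred essential package implies.

Everything is a deterministic function of the seed (mortality and supply
use decoupled substreams of `numpy.random.default_rng`), and generated
scenarios always pass full validation.

What the generator does **not** emulate: age/sex structure, calibration
to real country marginals, year-to-year dynamics, correlation between
income group and data quality, and any social or spiritual suffering
dimension. Passing tests on synthetic scenarios therefore demonstrate
the accounting is correct and invariant-preserving, not that any
particular country estimate is right — real estimates require real
envelopes and evidence-based coefficient tables as inputs.

## Numerical choices

* All internal arithmetic is float64 with no intermediate rounding;
  report writers round half-up via `decimal` (Python's builtin `round`
  is banker's rounding and would disagree on .5 ties).
* Scenario CSV round-trips are bit-exact: floats are written as shortest
  round-trip reprs and read with `float_precision="round_trip"`.
* Degenerate inputs raise named errors rather than returning NaN: zero
  patients (`ZeroNeedError`), zero symptom-days (`ZeroBurdenError`),
  zero requirement (`ZeroRequirementError`), no-data countries
  (`NoDataError`), population ≤ 0 and dangling references
  (`ScenarioValidationError` naming table/row/field).
* A (condition, status) cell with people in need but no symptom
  coefficient rows is a validation error in the burden stage (the bound
  would silently be wrong); the same situation in the encounter stage
  contributes zero (coefficient coverage there is a design choice about
  where care is delivered).

## Verification strategy and problem sizes

The test suite checks every stage against an independent brute-force
loop implementation (nested loops, no shared code) at 1e-9 relative
tolerance on 100 randomly built small scenarios (2–5 countries, 3–6
conditions), plus closed-loop recovery of planted supply fractions
f ∈ {0, 0.1, 0.5, 1.0, 1.2} and planted need fractions (exact), and
property suites (bound ordering, share normalization, methadone
invariance, linearity, monotonicity, aggregation associativity,
write/read identity, byte-identical reruns). Published arithmetic that
is internally consistent — regional totals, the per-100k
normalizations, the min–max staffing bands — is reproduced exactly from
the printed tables bundled in `palcare.datasets`. Small scenario sizes
keep the whole suite in seconds; the computations are linear algebra on
tiny tables, so nothing changes at full scale.

## Known limitations

* Published per-country estimates are not recomputable from first
  principles here: they depend on mortality extracts and appendix
  coefficient tables that are not reprinted. The package reproduces the
  printed derivations and proves the machinery on synthetic data.
* The two bounds bracket but do not estimate symptom-day burden; no
  within-day overlap model is attempted.
* DOME is a supply-side surrogate: it ignores procedural use (unless
  `procedural_fraction` is set), stock dynamics, and within-country
  distribution.
* A few published cells are internally inconsistent at the last printed
  digit (totals vs parts, per-100k vs count/population); the pipeline
  always computes from unrounded values and documents rather than
  reproduces those artifacts.
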