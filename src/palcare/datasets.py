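"""Published 2015 estimates for the WHO Eastern Mediterranean Region.

Two small reference tables of published country-level estimates, used by
the worked examples and the reproduction checks: the per-country counts
of people needing palliative care with their symptom-day bounds, and the
encounter volumes and staffing requirements for three countries of
different income levels.  These are *outputs* of the published analysis
carried here as printed (rounded) values; the pipeline's own estimates
come from scenario inputs, never from these tables.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["eamreg_2015_need_table", "eamreg_2015_workforce_table"]

_NEED_ROWS = [
    # country, income_group, at_most_days (millions), at_least_days (millions),
    # decedents (thousands), nondecedents (thousands), total (thousands)
    ("Afghanistan", "low", 40, 13, 95, 71, 166),
    ("Somalia", "low", 24, 8, 47, 51, 98),
    ("South Sudan", "low", 78, 23, 51, 201, 251),
    ("Egypt", "lower-middle", 142, 43, 254, 174, 428),
    ("Morocco", "lower-middle", 55, 17, 77, 87, 164),
    ("Pakistan", "lower-middle", 248, 75, 513, 355, 869),
    ("Syrian Arab Republic", "lower-middle", 26, 8, 51, 72, 123),
    ("Sudan", "lower-middle", 60, 19, 109, 120, 228),
    ("Tunisia", "lower-middle", 21, 7, 29, 34, 63),
    ("Yemen", "lower-middle", 26, 9, 56, 49, 109),
    ("Iran (Islamic Republic of)", "upper-middle", 125, 38, 155, 208, 363),
    ("Iraq", "upper-middle", 33, 11, 71, 72, 143),
    ("Lebanon", "upper-middle", 11, 3, 14, 17, 31),
    ("Jordan", "upper-middle", 8, 2, 12, 12, 24),
    ("Libya", "upper-middle", 8, 3, 13, 13, 26),
    ("Bahrain", "high", 1, 0, 1, 1, 2),
    ("Kuwait", "high", 2, 1, 3, 4, 7),
    ("Oman", "high", 3, 1, 4, 5, 9),
    ("Qatar", "high", 1, 0, 1, 2, 3),
    ("Saudi Arabia", "high", 24, 8, 40, 44, 84),
    ("United Arab Emirates", "high", 3, 1, 6, 5, 11),
]


def eamreg_2015_need_table() -> pd.DataFrame:
    """Per-country published 2015 need and symptom-day estimates.

    One row per country with data (Palestine, for which no data were
    available, is omitted).  Counts are as printed: symptom days in
    millions, people in thousands.
    """
    return pd.DataFrame(_NEED_ROWS, columns=[
        "country", "income_group",
        "at_most_symptom_days_millions", "at_least_symptom_days_millions",
        "decedents_thousands", "nondecedents_thousands", "total_thousands",
    ])


_WORKFORCE_COLUMNS = [
    "country", "income_group", "population", "decedents", "nondecedents",
    "referral_hospital_inpatient_days", "referral_hospital_outpatient_visits",
    "provincial_hospital_inpatient_days", "provincial_hospital_outpatient_visits",
    "district_hospital_inpatient_days", "district_hospital_outpatient_visits",
    "community_health_center_inpatient_days",
    "community_health_center_outpatient_visits",
    "home_visits",
    "fte_doctor", "fte_nurse", "fte_social_worker", "fte_spiritual_counsellor",
    "fte_psychologist_or_psychiatrist", "fte_physical_therapist",
    "fte_pharmacist", "fte_community_health_worker", "fte_clinical_support",
    "fte_nonclinical_support",
    # per-100,000 values as printed (two decimals); note a few printed cells
    # differ in the last decimal from recomputing count/population, because
    # the published counts were themselves rounded before printing.
    "printed_per_100k_doctor", "printed_per_100k_nurse",
    "printed_per_100k_social_worker", "printed_per_100k_spiritual_counsellor",
    "printed_per_100k_psychologist_or_psychiatrist",
    "printed_per_100k_physical_therapist", "printed_per_100k_pharmacist",
    "printed_per_100k_community_health_worker",
    "printed_per_100k_clinical_support", "printed_per_100k_nonclinical_support",
]

_WORKFORCE_ROWS = [
    ("Afghanistan", "low", 38_928_340, 93_373, 77_439,
     818_291, 194_418, 567_408, 164_497, 502_872, 353_407, 11_633, 375_581,
     5_431_684,
     722, 1443, 940, 112, 77, 27, 168, 3018, 12, 142,
     1.85, 3.71, 2.42, 0.29, 0.20, 0.07, 0.43, 7.75, 0.03, 0.36),
    ("Morocco", "lower-middle", 36_910_560, 76_109, 87_346,
     586_533, 264_207, 302_913, 215_410, 599_917, 473_602, 14_801, 566_372,
     5_431_684,
     682, 1588, 1051, 91, 49, 17, 164, 4096, 10, 119,
     1.85, 4.30, 2.85, 0.25, 0.13, 0.04, 0.44, 11.10, 0.03, 0.32),
    ("Jordan", "upper-middle", 10_203_140, 12_283, 11_753,
     95_847, 33_539, 48_218, 24_623, 86_206, 60_769, 2_229, 68_241,
     997_603,
     100, 222, 147, 14, 8, 3, 24, 554, 2, 18,
     0.98, 2.18, 1.44, 0.14, 0.08, 0.03, 0.23, 5.43, 0.02, 0.18),
]


def eamreg_2015_workforce_table() -> pd.DataFrame:
    """Published 2015 encounter volumes and FTE requirements, three countries.

    One low-income (Afghanistan), one lower-middle-income (Morocco) and
    one upper-middle-income (Jordan) country; FTE counts are absolute
    full-time equivalents per staff category.
    """
    return pd.DataFrame(_WORKFORCE_ROWS, columns=_WORKFORCE_COLUMNS)
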