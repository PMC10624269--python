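"""Controlled vocabularies for the serious health-related suffering framework.

The estimation framework rests on a closed list of 20 serious-illness
conditions (the ICD-10 groups that most commonly generate moderate or
severe suffering), 15 symptom types (11 physical, 4 psychological), five
care levels of a national health system, and 10 staff categories.  These
lists are closed enumerations: scenario validation rejects anything
outside them, which keeps every downstream join total.
"""

from __future__ import annotations

from enum import Enum
from typing import Literal

IncomeGroup = Literal["low", "lower-middle", "upper-middle", "high"]
INCOME_GROUPS: tuple[str, ...] = ("low", "lower-middle", "upper-middle", "high")

Status = Literal["decedent", "nondecedent"]
STATUSES: tuple[str, ...] = ("decedent", "nondecedent")

#: code -> display name for the 20 serious-illness conditions.
CONDITIONS: dict[str, str] = {
    "hiv": "HIV/AIDS",
    "neoplasms": "Malignant neoplasms",
    "leukemia": "Leukemia",
    "cerebrovascular": "Cerebrovascular disease",
    "dementia": "Dementia",
    "cihd": "Chronic ischemic heart disease",
    "nihd": "Non-ischemic heart disease",
    "lung": "Chronic lung disease",
    "liver": "Liver disease",
    "renal": "Renal failure",
    "tb": "Tuberculosis",
    "cns_inflammatory": "Inflammatory CNS disease",
    "cns_degenerative": "Degenerative CNS disease",
    "musculoskeletal": "Musculoskeletal disorders",
    "injuries": "Injuries, poisoning, external causes",
    "hemorrhagic_fevers": "Hemorrhagic fevers",
    "malnutrition": "Protein energy malnutrition",
    "congenital": "Congenital malformations",
    "prematurity": "Prematurity and birth trauma",
    "atherosclerosis": "Atherosclerosis",
}

CONDITION_CODES: tuple[str, ...] = tuple(CONDITIONS)

#: 11 physical symptom types.
PHYSICAL_SYMPTOMS: tuple[str, ...] = (
    "pain",
    "dyspnea",
    "fatigue",
    "weakness",
    "nausea_or_vomiting",
    "diarrhea",
    "constipation",
    "dry_mouth",
    "pruritus",
    "wounds_or_bleeding",
    "oral_lesions",
)

#: 4 psychological symptom types.
PSYCHOLOGICAL_SYMPTOMS: tuple[str, ...] = (
    "anxiety_or_worry",
    "depressed_mood",
    "confusion_or_delirium",
    "dementia_symptoms",
)

SYMPTOMS: tuple[str, ...] = PHYSICAL_SYMPTOMS + PSYCHOLOGICAL_SYMPTOMS


class CareLevel(str, Enum):
    """The five locations where a palliative care encounter can happen."""

    referral_hospital = "referral_hospital"
    provincial_hospital = "provincial_hospital"
    district_hospital = "district_hospital"
    community_health_center = "community_health_center"
    home = "home"


CARE_LEVELS: tuple[str, ...] = tuple(level.value for level in CareLevel)

#: Facility levels (everything except home care).
FACILITY_LEVELS: tuple[str, ...] = tuple(
    level for level in CARE_LEVELS if level != CareLevel.home.value
)

STAFF_CATEGORIES: tuple[str, ...] = (
    "doctor",
    "nurse",
    "social_worker",
    "spiritual_counsellor",
    "psychologist_or_psychiatrist",
    "physical_therapist",
    "pharmacist",
    "community_health_worker",
    "clinical_support",
    "nonclinical_support",
)
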