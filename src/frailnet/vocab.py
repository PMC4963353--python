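"""Controlled vocabulary for the elderly-cohort network.

Every analysis variable is categorical ("modalities" in the network sense):
four socio-demographic variables, one four-level GP frailty assessment and
fourteen dichotomous clinical categories obtained by grouping ICD-9-CM
discharge diagnoses.  Modality node labels follow the conventions used for
graph exports (``a75-79``, ``ElderlyCouple``, ``Circulatory``, ...).
"""

from __future__ import annotations

AGE_CLASSES: tuple[str, ...] = ("75-79", "80-84", "85-89", "90+")
AGE_LABELS: dict[str, str] = {a: f"a{a}" for a in AGE_CLASSES}

GENDERS: tuple[str, ...] = ("Male", "Female")

MARITAL_STATUSES: tuple[str, ...] = ("Married", "Unmarried", "Widowed")

FAMILY_STATUSES: tuple[str, ...] = (
    "NoCriticalFamily",         # living in a family without critical issues
    "ElderlyCouple",            # two self-sufficient elderly
    "ElderlyCaregiver",         # taking care of a non-self-sufficient subject
    "LivingAlone",
    "ElderlyInstitutionalized",  # living in an eldercare facility
)

# GP frailty assessment: not frail; pre-frail with social needs; pre-frail
# with health needs; frail (both health and social needs).
FRAILTY_STATUSES: tuple[str, ...] = ("NF", "PFSN", "PFHN", "FR")
FRAILTY_LABELS: dict[str, str] = {
    "NF": "NotFrail",
    "PFSN": "PFSN",
    "PFHN": "PFHN",
    "FR": "Frail",
}

# Clinical categories (one grouping level over ICD-9-CM chapters).
CLINICAL_CATEGORIES: tuple[str, ...] = (
    "InjuryPoisoning",
    "Blood",
    "Circulatory",
    "Digestive",
    "EndocrineMetabolic",
    "GenitoUrinary",
    "Infectious",
    "MentalIllness",
    "Musculoskeletal",
    "Neoplasms",
    "Nervous",
    "Respiratory",
    "Skin",
    "SignsSymptoms",
)

#: The 28 characteristic modalities (socio-demographic + clinical); frailty
#: statuses are counted separately, giving 32 possible non-patient nodes.
CHARACTERISTIC_MODALITIES: tuple[str, ...] = (
    tuple(AGE_LABELS[a] for a in AGE_CLASSES)
    + GENDERS
    + MARITAL_STATUSES
    + FAMILY_STATUSES
    + CLINICAL_CATEGORIES
)

ALL_MODALITY_NODES: tuple[str, ...] = CHARACTERISTIC_MODALITIES + tuple(
    FRAILTY_LABELS[f] for f in FRAILTY_STATUSES
)

# Named multi-morbidity profiles: the exact category sets reported for
# hospitalized patients carrying two or more clinical flags.  Order matters
# for reporting.
NAMED_PROFILES: tuple[tuple[str, frozenset[str]], ...] = (
    ("Circulatory + EndocrineMetabolic",
     frozenset({"Circulatory", "EndocrineMetabolic"})),
    ("Circulatory + Respiratory",
     frozenset({"Circulatory", "Respiratory"})),
    ("Circulatory + Digestive",
     frozenset({"Circulatory", "Digestive"})),
    ("Circulatory + InjuryPoisoning",
     frozenset({"Circulatory", "InjuryPoisoning"})),
    ("Circulatory + GenitoUrinary",
     frozenset({"Circulatory", "GenitoUrinary"})),
    ("Circulatory + EndocrineMetabolic + Respiratory",
     frozenset({"Circulatory", "EndocrineMetabolic", "Respiratory"})),
    ("Circulatory + Neoplasms",
     frozenset({"Circulatory", "Neoplasms"})),
    ("Neoplasms + Digestive",
     frozenset({"Neoplasms", "Digestive"})),
    ("Neoplasms + GenitoUrinary",
     frozenset({"Neoplasms", "GenitoUrinary"})),
    ("Circulatory + SignsSymptoms",
     frozenset({"Circulatory", "SignsSymptoms"})),
    ("Circulatory + Musculoskeletal",
     frozenset({"Circulatory", "Musculoskeletal"})),
    ("Circulatory + Nervous",
     frozenset({"Circulatory", "Nervous"})),
    ("Circulatory + Respiratory + GenitoUrinary",
     frozenset({"Circulatory", "Respiratory", "GenitoUrinary"})),
    ("Circulatory + MentalIllness",
     frozenset({"Circulatory", "MentalIllness"})),
    ("Circulatory + EndocrineMetabolic + GenitoUrinary",
     frozenset({"Circulatory", "EndocrineMetabolic", "GenitoUrinary"})),
)

OTHER_PROFILE_LABEL = "Other multi-morbid profiles"


def profile_name(categories: frozenset[str]) -> str:
    """Map an exact category set to its named profile, else the catch-all."""
    for name, members in NAMED_PROFILES:
        if categories == members:
            return name
    return OTHER_PROFILE_LABEL
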