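"""Default specialty and condition mapping tables.

Two editable tables drive the specialty logic:

* ``DEFAULT_SPECIALTY_CATEGORIES`` — provider specialty (fine taxonomy, as
  in a CMS-style directory) to the broad hospital ranking categories used
  by specialty hospital rankings.  The mapping is one-to-many: an internist
  plausibly maps to several ranking categories.
* ``DEFAULT_CONDITIONS`` — chronic-condition name to (i) the set of provider
  specialties that treat it and (ii) the plan-level treatment-score column
  it is correlated against.

Both ship as Python constants and round-trip through CSV so users can
substitute their own curated tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

RANKING_CATEGORIES = [
    "Cancer",
    "Cardiology & Heart Surgery",
    "Diabetes & Endocrinology",
    "Gynecology",
    "Pediatrics",
    "Psychiatry",
    "Orthopedics",
    "Neurology & Neurosurgery",
    "Gastroenterology & GI Surgery",
    "Geriatrics",
]

DEFAULT_SPECIALTY_CATEGORIES: dict[str, set[str]] = {
    "Internal Medicine": {"Cardiology & Heart Surgery", "Diabetes & Endocrinology",
                          "Gastroenterology & GI Surgery", "Geriatrics"},
    "Family Medicine": {"Geriatrics", "Pediatrics"},
    "Emergency Medicine": {"Cardiology & Heart Surgery"},
    "Pediatrics": {"Pediatrics"},
    "Neonatal Pediatrics": {"Pediatrics"},
    "Pediatrics Critical Care": {"Pediatrics"},
    "Pediatric Oncology": {"Pediatrics", "Cancer"},
    "Obstetrics and Gynecology": {"Gynecology"},
    "Gynecology Oncology": {"Gynecology", "Cancer"},
    "Cardiologist": {"Cardiology & Heart Surgery"},
    "Cardiovascular Diseases": {"Cardiology & Heart Surgery"},
    "Cardiac Rehabilitation": {"Cardiology & Heart Surgery"},
    "Cardiology Technician": {"Cardiology & Heart Surgery"},
    "Oncology": {"Cancer"},
    "Hematology & Oncology": {"Cancer"},
    "Radiation Oncology": {"Cancer"},
    "Endocrinology": {"Diabetes & Endocrinology"},
    "Diabetes and Metabolism": {"Diabetes & Endocrinology"},
    "Diabetes Educator": {"Diabetes & Endocrinology"},
    "Psychologist": {"Psychiatry"},
    "Counselor": {"Psychiatry"},
    "Psychoanalyst": {"Psychiatry"},
    "Psychoanalysis": {"Psychiatry"},
    "Clinical Neuropsychologist": {"Psychiatry", "Neurology & Neurosurgery"},
    "Marriage and Family Therapist": {"Psychiatry"},
    "Orthopedic Surgery": {"Orthopedics"},
    "Neurology": {"Neurology & Neurosurgery"},
    "Dermatology": set(),  # no ranking category covers it
    "Gastroenterology": {"Gastroenterology & GI Surgery"},
}


@dataclass(frozen=True)
class Condition:
    """One condition row: specialties treating it and the plan score column."""

    name: str
    specialties: frozenset[str]
    score_column: str


DEFAULT_CONDITIONS: list[Condition] = [
    Condition("Women's health",
              frozenset({"Obstetrics and Gynecology", "Gynecology Oncology"}),
              "womens_reproductive_score"),
    Condition("Mental and behavioral health",
              frozenset({"Counselor", "Psychoanalyst", "Clinical Neuropsychologist",
                         "Psychologist", "Psychoanalysis", "Marriage and Family Therapist"}),
              "mental_behavioral_score"),
    Condition("Cancer screening",
              frozenset({"Pediatric Oncology", "Oncology", "Hematology & Oncology",
                         "Radiation Oncology"}),
              "cancer_screening_score"),
    Condition("Heart disease",
              frozenset({"Cardiologist", "Cardiac Rehabilitation", "Cardiology Technician",
                         "Cardiovascular Diseases"}),
              "heart_disease_treatment_score"),
    Condition("Children and adolescent health",
              frozenset({"Pediatrics", "Neonatal Pediatrics", "Pediatrics Critical Care"}),
              "children_adolescents_score"),
    Condition("Diabetes",
              frozenset({"Diabetes Educator", "Endocrinology", "Diabetes and Metabolism"}),
              "diabetes_treatment_score"),
]


@dataclass
class ConditionMap:
    """Condition -> member specialties and plan treatment-score column."""

    conditions: list[Condition] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))

    def validate(self, plan_columns: list[str]) -> None:
        missing = [c.name for c in self.conditions if c.score_column not in plan_columns]
        if missing:
            raise ValueError(f"conditions with no matching plan score column: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.name, ";".join(sorted(c.specialties)), c.score_column)
             for c in self.conditions],
            columns=["condition", "specialties", "score_column"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionMap":
        df = pd.read_csv(path)
        conds = [Condition(r.condition, frozenset(r.specialties.split(";")), r.score_column)
                 for r in df.itertuples()]
        return cls(conds)


def specialty_map_frame(entries: dict[str, set[str]]) -> pd.DataFrame:
    """Flatten a specialty->categories mapping into a two-column table."""
    rows = [(spec, cat) for spec, cats in entries.items() for cat in sorted(cats)]
    return pd.DataFrame(rows, columns=["specialty", "category"])


def specialty_map_from_frame(df: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.specialty, set()).add(r.category)
    return out
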