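"""World configuration: sizes, marginal rates, noise and planted effects.

The generator is parameterised by a :class:`WorldConfig`.  Its defaults encode
the empirical marginals of the crawled provider/plan universe this package
emulates: 4% of providers hold a peer-nominated award, 42% have zero inbound
referrals, roughly 2.6% of listed hospitals carry a specialty ranking, about
17% of plans have incomplete score data, mean patient rating near 82 on a
0-100 scale, and providers accept 1-8 insurers with mean 1.7.

``planted_effects`` plants target Pearson correlations between plan-level
aggregates of provider attributes and the plan consumer-satisfaction score;
``condition_effects`` does the same for condition-restricted provider ratings
against the condition's treatment-score column.  Targets are calibrated
against the realized plan-level aggregates, so the planted r is exact up to
sampling error in the downstream estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """A WorldConfig field failed validation; the message names the field."""


#: Channels a planted effect may target, and the plan score column each
#: condition effect targets, are fixed by the aggregation stage.
PLAN_ATTRIBUTE_CHANNELS = (
    "mean_rating",
    "mean_referrals",
    "cc_ratio",
    "mean_hospital_rank",
    "mean_relative_cost",
)

DEFAULT_STATE_POPULATIONS: dict[str, int] = {
    "CA": 39_000_000, "TX": 29_000_000, "FL": 21_000_000, "NY": 20_000_000,
    "PA": 13_000_000, "IL": 12_800_000, "OH": 11_800_000, "NJ": 9_300_000,
    "WA": 7_700_000, "MA": 7_000_000,
}

DEFAULT_SPECIALTY_WEIGHTS: dict[str, float] = {
    "Internal Medicine": 0.13, "Family Medicine": 0.11, "Emergency Medicine": 0.05,
    "Pediatrics": 0.07, "Neonatal Pediatrics": 0.015, "Pediatrics Critical Care": 0.01,
    "Obstetrics and Gynecology": 0.05, "Gynecology Oncology": 0.01,
    "Cardiologist": 0.05, "Cardiovascular Diseases": 0.02, "Cardiac Rehabilitation": 0.01,
    "Oncology": 0.04, "Hematology & Oncology": 0.02, "Radiation Oncology": 0.01,
    "Pediatric Oncology": 0.01,
    "Endocrinology": 0.04, "Diabetes and Metabolism": 0.025, "Diabetes Educator": 0.015,
    "Psychologist": 0.05, "Counselor": 0.03, "Psychoanalyst": 0.01,
    "Clinical Neuropsychologist": 0.01, "Marriage and Family Therapist": 0.02,
    "Orthopedic Surgery": 0.05, "Dermatology": 0.04, "Neurology": 0.04,
    "Gastroenterology": 0.04,
}


@dataclass
class PlantedEffect:
    """Association between a plan-level aggregate and a plan score column.

    Either ``target_r`` (the calibrated route) or an explicit ``slope`` and
    ``noise_sd`` may be given; ``target_r`` wins when both are present.
    """

    target_r: float | None = None
    slope: float | None = None
    noise_sd: float | None = None

    def validate(self, name: str) -> None:
        if self.target_r is not None:
            if not -1.0 < self.target_r < 1.0:
                raise ConfigError(f"planted_effects[{name!r}].target_r must be in (-1, 1)")
        elif self.slope is None:
            raise ConfigError(f"planted_effects[{name!r}] needs target_r or slope")


@dataclass
class NameNoise:
    """Perturbation applied when cloning the directory into site profiles.

    ``max_edits`` bounds the number of single-character edits per string
    field (an int, or a per-field mapping); ``dropout`` is the probability a
    field value is replaced with absent; ``distractor_rate`` adds site-only
    records with no true counterpart, as a fraction of the directory size.
    """

    max_edits: int | Mapping[str, int] = 2
    dropout: float | Mapping[str, float] = 0.05
    distractor_rate: float = 0.10

    STRING_FIELDS = ("first_name", "middle_name", "last_name", "address", "medical_school")
    DROPPABLE_FIELDS = STRING_FIELDS + ("graduation_year",)

    def edits_for(self, fld: str) -> int:
        if isinstance(self.max_edits, Mapping):
            return int(self.max_edits.get(fld, 0))
        return int(self.max_edits)

    def dropout_for(self, fld: str) -> float:
        if isinstance(self.dropout, Mapping):
            return float(self.dropout.get(fld, 0.0))
        return float(self.dropout)

    def validate(self) -> None:
        for fld in self.STRING_FIELDS:
            if self.edits_for(fld) < 0:
                raise ConfigError(f"name_noise.max_edits[{fld!r}] must be >= 0")
        for fld in self.DROPPABLE_FIELDS:
            if not 0.0 <= self.dropout_for(fld) <= 1.0:
                raise ConfigError(f"name_noise.dropout[{fld!r}] must be in [0, 1]")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise ConfigError("name_noise.distractor_rate must be in [0, 1]")


def _default_planted() -> dict[str, PlantedEffect]:
    return {
        "mean_rating": PlantedEffect(target_r=0.376),
        "mean_referrals": PlantedEffect(target_r=0.031),
        "cc_ratio": PlantedEffect(target_r=0.183),
        "mean_hospital_rank": PlantedEffect(target_r=-0.108),
        "mean_relative_cost": PlantedEffect(target_r=0.266),
    }


def _default_condition_effects() -> dict[str, PlantedEffect]:
    return {
        "Women's health": PlantedEffect(target_r=0.135),
        "Mental and behavioral health": PlantedEffect(target_r=0.112),
        "Cancer screening": PlantedEffect(target_r=0.112),
        "Heart disease": PlantedEffect(target_r=-0.002),
        "Children and adolescent health": PlantedEffect(target_r=-0.083),
        "Diabetes": PlantedEffect(target_r=-0.259),
    }


@dataclass
class WorldConfig:
    n_providers: int = 2000
    n_plans: int = 300
    n_hospitals: int = 200
    states: list[str] = field(default_factory=lambda: list(DEFAULT_STATE_POPULATIONS))
    state_populations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STATE_POPULATIONS))
    specialties: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIALTY_WEIGHTS))
    frac_ranked_hospitals: float = 50 / 1956
    frac_castle_connolly: float = 0.04
    frac_zero_referrals: float = 0.42
    frac_reviewed: float = 0.30
    frac_incomplete_plans: float = 213 / 1264
    rating_mean: float = 82.0
    rating_sd: float = 12.0
    satisfaction_mean: float = 78.0
    satisfaction_sd: float = 8.0
    mean_extra_insurers: float = 0.7     # accepted insurers = 1 + Poisson, capped at 8
    name_noise: NameNoise = field(default_factory=NameNoise)
    planted_effects: dict[str, PlantedEffect] = field(default_factory=_default_planted)
    condition_effects: dict[str, PlantedEffect] = field(
        default_factory=_default_condition_effects)
    state_heterogeneity: float = 4.0     # sd (score points) of state-level intercepts
    seed: int = 0

    def validate(self) -> None:
        for fld in ("n_providers", "n_plans", "n_hospitals"):
            if getattr(self, fld) <= 0:
                raise ConfigError(f"{fld} must be positive")
        for fld in ("frac_ranked_hospitals", "frac_castle_connolly",
                    "frac_zero_referrals", "frac_reviewed", "frac_incomplete_plans"):
            if not 0.0 <= getattr(self, fld) <= 1.0:
                raise ConfigError(f"{fld} must be in [0, 1]")
        if not self.states:
            raise ConfigError("states must be nonempty")
        missing = [s for s in self.states if s not in self.state_populations]
        if missing:
            raise ConfigError(f"state_populations missing entries for {missing}")
        if not self.specialties:
            raise ConfigError("specialties must be nonempty")
        if self.state_heterogeneity < 0:
            raise ConfigError("state_heterogeneity must be >= 0")
        if self.rating_sd <= 0 or self.satisfaction_sd <= 0:
            raise ConfigError("rating_sd and satisfaction_sd must be positive")
        self.name_noise.validate()
        total_r2 = 0.0
        for name, eff in self.planted_effects.items():
            if name not in PLAN_ATTRIBUTE_CHANNELS:
                raise ConfigError(f"unknown planted_effects channel {name!r}")
            eff.validate(name)
            if eff.target_r is not None:
                total_r2 += eff.target_r ** 2
        if total_r2 >= 1.0:
            raise ConfigError("sum of squared planted target_r values must be < 1")
        for name, eff in self.condition_effects.items():
            eff.validate(name)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        d = dict(d)
        if "name_noise" in d and isinstance(d["name_noise"], Mapping):
            d["name_noise"] = NameNoise(**d["name_noise"])
        for key in ("planted_effects", "condition_effects"):
            if key in d:
                d[key] = {k: v if isinstance(v, PlantedEffect) else PlantedEffect(**v)
                          for k, v in d[key].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
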