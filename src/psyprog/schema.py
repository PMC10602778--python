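"""Feature schema: the typed catalogue of every cohort column.

Mirrors the predictor table of the emulated study: seven static modalities
(demographic, diagnostic, lifestyle, somatic, treatment, CDSS, SWN), the 48
binary MINI items, and three dynamic modalities (PANSS 30, PSP 5, CGI 2)
recorded at baseline and weeks 2, 3, 5, 6, 8. Each feature is continuous,
categorical, or binary; dynamic features materialize as visit-suffixed
columns (``panss_p1_w0`` .. ``panss_p1_w8``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .config import VISIT_WEEKS
from .mini_items import MINI_COLUMNS, MINI_LABELS

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
BINARY = "binary"

STATIC_MODALITIES = ("demographic", "diagnostic", "lifestyle", "somatic",
                     "treatment", "cdss", "swn", "mini")
DYNAMIC_MODALITIES = ("panss", "psp", "cgi")

#: PANSS item short names: positive P1-P7, negative N1-N7, general G1-G16
PANSS_ITEMS = ([f"p{i}" for i in range(1, 8)] + [f"n{i}" for i in range(1, 8)]
               + [f"g{i}" for i in range(1, 17)])
#: severity-rule items for symptomatic remission (all must be <= 3)
ANDREASEN_ITEMS = ("p1", "p2", "p3", "n1", "n4", "n6", "g5", "g9")

PSP_FEATURES = ["psp_dom1", "psp_dom2", "psp_dom3", "psp_dom4", "psp_total"]
CGI_FEATURES = ["cgi_severity", "cgi_improvement"]

#: fixed instrument bounds used to scale dynamic features into [0, 1]
INSTRUMENT_BOUNDS = {"panss": (1.0, 7.0), "psp_dom": (0.0, 6.0),
                     "psp_total": (0.0, 100.0), "cgi": (1.0, 7.0)}


@dataclass
class FeatureSpec:
    name: str
    modality: str
    value_type: str
    dynamic: bool = False
    categories: tuple[str, ...] = ()
    label: str = ""

    def columns(self) -> list[str]:
        """Concrete table columns (visit-suffixed when dynamic)."""
        if self.dynamic:
            return [f"{self.name}_w{w}" for w in VISIT_WEEKS]
        return [self.name]


@dataclass
class FeatureSchema:
    features: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name = {f.name: f for f in self.features}
        if len(self._by_name) != len(self.features):
            raise ValueError("duplicate feature names in schema")

    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    def select(self, *, modality: str | None = None,
               dynamic: bool | None = None) -> list[FeatureSpec]:
        out = self.features
        if modality is not None:
            out = [f for f in out if f.modality == modality]
        if dynamic is not None:
            out = [f for f in out if f.dynamic == dynamic]
        return out

    @property
    def static_features(self) -> list[FeatureSpec]:
        return self.select(dynamic=False)

    @property
    def dynamic_features(self) -> list[FeatureSpec]:
        return self.select(dynamic=True)

    def to_json(self, path: str | Path) -> None:
        payload = {"features": [asdict(f) for f in self.features],
                   "visit_weeks": list(VISIT_WEEKS)}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        feats = [FeatureSpec(**{**f, "categories": tuple(f["categories"])})
                 for f in payload["features"]]
        return cls(feats)


def _cat(name: str, modality: str, *categories: str) -> FeatureSpec:
    return FeatureSpec(name, modality, CATEGORICAL, categories=tuple(categories))


def _con(name: str, modality: str) -> FeatureSpec:
    return FeatureSpec(name, modality, CONTINUOUS)


def _bin(name: str, modality: str) -> FeatureSpec:
    return FeatureSpec(name, modality, BINARY)


def default_schema() -> FeatureSchema:
    """The default predictor schema (static modalities + MINI + dynamics)."""
    occupations = ("none", "manual", "clerical", "professional", "student")
    degrees = ("none", "primary", "secondary", "tertiary")
    feats: list[FeatureSpec] = [
        # demographic (20)
        _con("age", "demographic"),
        _bin("sex_male", "demographic"),
        _cat("race", "demographic", "white", "black", "asian", "other"),
        _bin("immigration_status", "demographic"),
        _bin("marital_status", "demographic"),
        _bin("divorce_status", "demographic"),
        _bin("occupation_status", "demographic"),
        _cat("occupation_type", "demographic", *occupations),
        _bin("previous_occupation_status", "demographic"),
        _cat("previous_occupation_type", "demographic", *occupations),
        _cat("father_occupation", "demographic", *occupations),
        _cat("mother_occupation", "demographic", *occupations),
        _con("years_education", "demographic"),
        _cat("highest_education", "demographic", *degrees),
        _cat("father_highest_degree", "demographic", *degrees),
        _cat("mother_highest_degree", "demographic", *degrees),
        _bin("living_status", "demographic"),
        _cat("dwelling", "demographic", "house", "apartment", "institution", "other"),
        _cat("income_source", "demographic", "employment", "family", "benefits", "none"),
        _cat("living_environment", "demographic", "urban", "suburban", "rural"),
        # diagnostic
        _cat("dsm_classification", "diagnostic",
             "schizophrenia", "schizophreniform", "schizoaffective"),
        _con("episode_duration_months", "diagnostic"),
        _cat("current_psychiatric_treatment", "diagnostic",
             "none", "outpatient", "inpatient"),
        _bin("psychosocial_interventions", "diagnostic"),
        _cat("estimated_prognosis", "diagnostic", "good", "fair", "poor"),
        _bin("admitted", "diagnostic"),
        # lifestyle (7)
        _bin("recreational_drugs_history", "lifestyle"),
        _bin("recreational_drugs_recent", "lifestyle"),
        _con("caffeine_per_day", "lifestyle"),
        _cat("last_caffeine", "lifestyle", "today", "this_week", "longer"),
        _bin("drink_alcohol", "lifestyle"),
        _cat("alcohol_last_year", "lifestyle", "none", "monthly", "weekly", "daily"),
        _bin("smoking_status", "lifestyle"),
        # somatic (11)
        _con("height_cm", "somatic"),
        _con("weight_kg", "somatic"),
        _con("waist_cm", "somatic"),
        _con("hip_cm", "somatic"),
        _con("bmi", "somatic"),
        _con("systolic_bp", "somatic"),
        _con("diastolic_bp", "somatic"),
        _con("pulse", "somatic"),
        _bin("ecg_abnormality", "somatic"),
        _cat("last_mealtime", "somatic", "lt_2h", "2_6h", "gt_6h"),
        _cat("last_meal_type", "somatic", "snack", "light", "full"),
        # treatment (1)
        _con("medication_dosage", "treatment"),
    ]
    feats += [_con(f"cdss_{i}", "cdss") for i in range(1, 10)]
    feats += [_con(f"swn_{i:02d}", "swn") for i in range(1, 21)]
    feats += [FeatureSpec(col, "mini", BINARY, label=lab)
              for col, lab in zip(MINI_COLUMNS, MINI_LABELS)]
    feats += [FeatureSpec(f"panss_{it}", "panss", CONTINUOUS, dynamic=True)
              for it in PANSS_ITEMS]
    feats += [FeatureSpec(n, "psp", CONTINUOUS, dynamic=True) for n in PSP_FEATURES]
    feats += [FeatureSpec(n, "cgi", CONTINUOUS, dynamic=True) for n in CGI_FEATURES]
    return FeatureSchema(feats)


def dynamic_bounds(spec: FeatureSpec) -> tuple[float, float]:
    """Instrument range of a dynamic feature, used for fixed [0,1] scaling."""
    if spec.modality == "panss":
        return INSTRUMENT_BOUNDS["panss"]
    if spec.modality == "psp":
        return (INSTRUMENT_BOUNDS["psp_total"] if spec.name == "psp_total"
                else INSTRUMENT_BOUNDS["psp_dom"])
    if spec.modality == "cgi":
        return INSTRUMENT_BOUNDS["cgi"]
    raise ValueError(f"not a dynamic feature: {spec.name}")
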