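"""Knowledge base: controlled vocabulary, medication and trigger lexicons,
and risk-factor extraction rules.

The vocabulary holds single and dual tokens derived by tokenising, combining
and filtering source clinical terms (ICD-9-CM 249/250 rubric descriptions,
SNOMED/MeSH-style synonyms, custom phrases).  Trigger lexicons drive the
removal of negated and family-history segments before any term matching.
Risk-factor rules are ordered regular expressions mapping unstructured
phrases (BMI lines, height/weight pairs, blood-pressure readings, smoking and
alcohol mentions) onto a small set of categories.

The default knowledge base shipped here is a curated, reduced lexicon built
by the same construction procedure a full deployment would use on the
complete terminology sources; the lexicon file is a first-class input so a
site can substitute its own.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "VocabularyTerm",
    "TriggerLexicon",
    "MedicationEntry",
    "RiskFactorRule",
    "KnowledgeBase",
    "build_vocabulary",
    "tokenize",
    "categorize_bmi",
    "derive_bmi",
    "default_knowledge_base",
    "load_kb",
    "save_kb",
    "DEFAULT_STOP_WORDS",
    "BMI_CATEGORIES",
    "RISK_FACTOR_CATEGORIES",
]

# Small fixed English stop-word list (configurable at KB build time).
DEFAULT_STOP_WORDS = frozenset(
    """a an and are as at be but by for from has have he her his if in into is
    it its not of on or she such that the their then there these they this to
    was were will with without""".split()
)

# WHO BMI classification, half-open intervals [lo, hi).
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obesity")
_BMI_CUTS = (18.5, 25.0, 30.0)

RISK_FACTOR_CATEGORIES = {
    "bmi": list(BMI_CATEGORIES),
    "smoking": ["never", "former", "current"],
    "alcohol_use": ["none", "use", "disorder"],
    "high_blood_pressure": ["present"],
    "clinical_history_dm": ["present"],
}

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[-'][a-z0-9]+)*")


@dataclass(frozen=True)
class VocabularyTerm:
    surface: str
    n_tokens: int
    source: str = "custom"
    concept_group: str = "dm_direct"

    def __post_init__(self):
        if not self.surface or self.surface != self.surface.lower():
            raise ValueError(f"term surface must be non-empty lowercase: {self.surface!r}")
        if self.n_tokens != len(self.surface.split()):
            raise ValueError(f"n_tokens mismatch for {self.surface!r}")
        if self.n_tokens not in (1, 2):
            raise ValueError("only single and dual tokens are supported")


@dataclass(frozen=True)
class TriggerLexicon:
    kind: str  # "negation" | "family_history"
    triggers: frozenset[str]

    def __post_init__(self):
        if self.kind not in ("negation", "family_history"):
            raise ValueError(f"unknown trigger lexicon kind: {self.kind!r}")
        trig = frozenset(t.lower() for t in self.triggers)
        if not trig or "" in trig:
            raise ValueError("trigger lexicon must be non-empty with no empty trigger")
        object.__setattr__(self, "triggers", trig)


@dataclass(frozen=True)
class MedicationEntry:
    name: str
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.name:
            raise ValueError("medication name must be non-empty")
        object.__setattr__(self, "name", self.name.lower())
        syns = frozenset(s.lower() for s in self.synonyms) - {self.name}
        object.__setattr__(self, "synonyms", syns)

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.name, *sorted(self.synonyms))


@dataclass(frozen=True)
class RiskFactorRule:
    """Ordered regex patterns for one risk factor; first match wins.

    ``value_map`` maps a pattern string to either a literal category or a
    computed sentinel: ``"@bmi"`` (named group ``value`` is a BMI, kg/m²),
    ``"@bmi_hw"`` (groups ``height``/``hunit``/``weight``/``wunit``), and
    ``"@bp"`` (groups ``sys``/``dia``; hypertensive readings map to
    ``present``).
    """

    factor: str
    patterns: tuple[str, ...]
    value_map: dict

    def __post_init__(self):
        if self.factor not in RISK_FACTOR_CATEGORIES:
            raise ValueError(f"unknown risk factor: {self.factor!r}")
        object.__setattr__(self, "patterns", tuple(self.patterns))
        for pat in self.patterns:
            re.compile(pat, re.IGNORECASE)  # raises on malformed pattern
            if pat not in self.value_map:
                raise ValueError(f"pattern without value mapping: {pat!r}")
        cats = set(RISK_FACTOR_CATEGORIES[self.factor])
        for val in self.value_map.values():
            if not (val in cats or str(val).startswith("@")):
                raise ValueError(f"category {val!r} not allowed for factor {self.factor}")

    def compiled(self) -> list[tuple[re.Pattern, object]]:
        return [(re.compile(p, re.IGNORECASE), self.value_map[p]) for p in self.patterns]


@dataclass(frozen=True)
class KnowledgeBase:
    terms: tuple[VocabularyTerm, ...]
    medications: tuple[MedicationEntry, ...]
    negation: TriggerLexicon
    family: TriggerLexicon
    risk_rules: tuple[RiskFactorRule, ...]
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "medications", tuple(self.medications))
        object.__setattr__(self, "risk_rules", tuple(self.risk_rules))
        object.__setattr__(self, "stop_words", frozenset(self.stop_words))
        surfaces = [t.surface for t in self.terms]
        if len(surfaces) != len(set(surfaces)):
            raise ValueError("duplicate vocabulary term surfaces")
        if self.negation.kind != "negation" or self.family.kind != "family_history":
            raise ValueError("trigger lexicons assigned to the wrong slots")

    @property
    def term_surfaces(self) -> list[str]:
        return [t.surface for t in self.terms]

    @property
    def medication_names(self) -> list[str]:
        return [m.name for m in self.medications]


def tokenize(text: str) -> list[str]:
    """Lowercase and split on whitespace, stripping punctuation but keeping
    intra-word hyphens/apostrophes and digits ("type 2" must survive)."""
    return _TOKEN_RE.findall(text.lower())


def build_vocabulary(raw_terms, stop_words=DEFAULT_STOP_WORDS, *, source="custom",
                     concept_group="dm_direct") -> list[VocabularyTerm]:
    """Tokenize, combine and filter source terms into a deduplicated
    controlled vocabulary of unigrams and adjacent bigrams.

    Any candidate containing a stop word (as a whole token) is removed.
    Output order is lexicographic, hence deterministic.
    """
    raw_terms = list(raw_terms)
    if not raw_terms:
        raise ValueError("no source terms")
    stop = {w.lower() for w in stop_words}
    surfaces: set[str] = set()
    for raw in raw_terms:
        toks = tokenize(raw)
        for tok in toks:
            if tok not in stop:
                surfaces.add(tok)
        for a, b in zip(toks, toks[1:]):
            if a not in stop and b not in stop:
                surfaces.add(f"{a} {b}")
    return [
        VocabularyTerm(surface=s, n_tokens=len(s.split()), source=source,
                       concept_group=concept_group)
        for s in sorted(surfaces)
    ]


def categorize_bmi(bmi: float) -> str:
    """WHO BMI class: underweight < 18.5 ≤ normal < 25 ≤ overweight < 30 ≤ obesity."""
    if not (isinstance(bmi, (int, float)) and math.isfinite(bmi)) or bmi <= 0:
        raise ValueError(f"BMI must be a positive finite number, got {bmi!r}")
    for cut, cat in zip(_BMI_CUTS, BMI_CATEGORIES):
        if bmi < cut:
            return cat
    return BMI_CATEGORIES[-1]


_LENGTH_TO_M = {"m": 1.0, "meter": 1.0, "meters": 1.0, "cm": 0.01, "in": 0.0254,
                "inch": 0.0254, "inches": 0.0254, "ft": 0.3048}
_MASS_TO_KG = {"kg": 1.0, "kgs": 1.0, "kilograms": 1.0, "lb": 0.45359237,
               "lbs": 0.45359237, "pounds": 0.45359237}


def derive_bmi(height: float, weight: float, *, height_unit: str = "m",
               weight_unit: str = "kg") -> float:
    """BMI (kg/m²) from height and weight with explicit units."""
    try:
        h = float(height) * _LENGTH_TO_M[height_unit.lower()]
        w = float(weight) * _MASS_TO_KG[weight_unit.lower()]
    except KeyError as exc:
        raise ValueError(f"unknown unit: {exc}") from exc
    if not (math.isfinite(h) and math.isfinite(w)) or h <= 0 or w <= 0:
        raise ValueError("height and weight must be positive")
    return w / (h * h)


# --------------------------------------------------------------------------
# Default lexicons
# --------------------------------------------------------------------------

# ICD-9-CM 249/250 rubric descriptions plus common clinical DM phrases; the
# controlled vocabulary is derived from these with build_vocabulary.
_ICD_RUBRIC_DESCRIPTIONS = [
    "Secondary diabetes mellitus without mention of complication",
    "Secondary diabetes mellitus with ketoacidosis",
    "Secondary diabetes mellitus with hyperosmolarity",
    "Secondary diabetes mellitus with renal manifestations",
    "Secondary diabetes mellitus with ophthalmic manifestations",
    "Secondary diabetes mellitus with neurological manifestations",
    "Secondary diabetes mellitus with peripheral circulatory disorders",
    "Diabetes mellitus without mention of complication",
    "Diabetes with ketoacidosis",
    "Diabetes with hyperosmolarity",
    "Diabetes with renal manifestations",
    "Diabetes with ophthalmic manifestations",
    "Diabetes with neurological manifestations",
    "Diabetes with peripheral circulatory disorders",
    "Diabetes with other specified manifestations",
    "Diabetes mellitus type 1",
    "Diabetes mellitus type 2",
    "type i diabetes",
    "type ii diabetes",
    "juvenile type diabetes",
    "adult onset diabetes",
    "insulin dependent diabetes mellitus",
    "non insulin dependent diabetes mellitus",
]

_CLINICAL_DM_PHRASES = [
    "diabetic patient",
    "diabetic retinopathy",
    "diabetic nephropathy",
    "diabetic neuropathy",
    "diabetic polyneuropathy",
    "diabetic ketoacidosis",
    "diabetic foot ulcer",
    "diabetic gastroparesis",
    "poorly controlled diabetes",
    "uncontrolled diabetes",
    "gestational diabetes",
    "hyperglycemia",
    "elevated hba1c",
    "hba1c elevated",
    "elevated blood glucose",
    "glucose intolerance",
    "impaired fasting glucose",
    "insulin resistance",
    "glycemic control",
    "blood sugar elevated",
    "dm2",
    "niddm",
    "iddm",
]

_DEFAULT_MEDICATIONS = [
    "metformin", "insulin", "glipizide", "glyburide", "glimepiride",
    "pioglitazone", "rosiglitazone", "sitagliptin", "saxagliptin",
    "linagliptin", "exenatide", "liraglutide", "canagliflozin",
    "dapagliflozin", "empagliflozin", "acarbose", "nateglinide",
    "repaglinide", "tolbutamide", "chlorpropamide", "glargine", "lispro",
    "aspart", "detemir",
]

# Negation triggers: a reduced NegEx-style phrase set.  Segment scope means a
# trigger anywhere in a basic unit removes the whole unit.
_DEFAULT_NEGATION = [
    "no", "not", "denies", "denied", "denying", "negative for",
    "no evidence of", "no history of", "without evidence of", "ruled out",
    "rules out", "rule out", "free of", "absence of", "never had",
    "no signs of", "does not have", "doesn't have", "unlikely", "resolved",
]

_DEFAULT_FAMILY = [
    "mother", "father", "brother", "sister", "grandmother", "grandfather",
    "aunt", "uncle", "cousin", "sibling", "parent", "maternal", "paternal",
    "family history", "fam hx", "fh",
]

_NUM = r"(\d{1,3}(?:\.\d+)?)"


def _default_risk_rules() -> list[RiskFactorRule]:
    bmi_direct = rf"\bbmi\s*(?:is|of|:|=)?\s*(?P<value>{_NUM})"
    bmi_hw = (
        rf"\b(?:ht|height)\s*:?\s*(?P<height>{_NUM})\s*(?P<hunit>m|cm|in|inches)\b"
        rf".{{0,40}}?\b(?:wt|weight)\s*:?\s*(?P<weight>{_NUM})\s*(?P<wunit>kg|kgs|lb|lbs)\b"
    )
    bp_reading = r"\b(?:bp|blood pressure)\s*:?\s*(?P<sys>\d{2,3})\s*/\s*(?P<dia>\d{2,3})\b"
    htn_phrase = r"\b(?:hypertension|htn|high blood pressure|elevated blood pressure)\b"
    return [
        RiskFactorRule("bmi", (bmi_direct, bmi_hw),
                       {bmi_direct: "@bmi", bmi_hw: "@bmi_hw"}),
        RiskFactorRule(
            "smoking",
            (r"\b(?:never smoker|never smoked|nonsmoker|non-smoker)\b",
             r"\b(?:former smoker|ex-smoker|quit smoking|past smoker)\b",
             r"\b(?:current smoker|smokes|smoker|tobacco use|cigarette)\b"),
            {r"\b(?:never smoker|never smoked|nonsmoker|non-smoker)\b": "never",
             r"\b(?:former smoker|ex-smoker|quit smoking|past smoker)\b": "former",
             r"\b(?:current smoker|smokes|smoker|tobacco use|cigarette)\b": "current"},
        ),
        RiskFactorRule(
            "alcohol_use",
            (r"\b(?:alcohol use disorder|alcoholism|alcohol abuse|alcohol dependence)\b",
             r"\b(?:drinks alcohol|alcohol use|social alcohol|occasional alcohol|etoh use)\b",
             r"\b(?:abstains from alcohol|teetotal)\b"),
            {r"\b(?:alcohol use disorder|alcoholism|alcohol abuse|alcohol dependence)\b": "disorder",
             r"\b(?:drinks alcohol|alcohol use|social alcohol|occasional alcohol|etoh use)\b": "use",
             r"\b(?:abstains from alcohol|teetotal)\b": "none"},
        ),
        RiskFactorRule("high_blood_pressure", (htn_phrase, bp_reading),
                       {htn_phrase: "present", bp_reading: "@bp"}),
        RiskFactorRule(
            "clinical_history_dm",
            (r"\bhistory of diabetes\b|\bh/o diabetes\b|\bknown diabetic\b|\bhx of dm\b",),
            {r"\bhistory of diabetes\b|\bh/o diabetes\b|\bknown diabetic\b|\bhx of dm\b": "present"},
        ),
    ]


def default_knowledge_base(stop_words=DEFAULT_STOP_WORDS) -> KnowledgeBase:
    """The curated default knowledge base (reduced controlled vocabulary)."""
    terms = {}
    for t in build_vocabulary(_ICD_RUBRIC_DESCRIPTIONS, stop_words,
                              source="icd_description", concept_group="dm_direct"):
        terms[t.surface] = t
    for t in build_vocabulary(_CLINICAL_DM_PHRASES, stop_words,
                              source="custom", concept_group="clinical"):
        terms.setdefault(t.surface, t)
    return KnowledgeBase(
        terms=tuple(terms[s] for s in sorted(terms)),
        medications=tuple(MedicationEntry(m) for m in _DEFAULT_MEDICATIONS),
        negation=TriggerLexicon("negation", frozenset(_DEFAULT_NEGATION)),
        family=TriggerLexicon("family_history", frozenset(_DEFAULT_FAMILY)),
        risk_rules=tuple(_default_risk_rules()),
        stop_words=frozenset(stop_words),
    )


# --------------------------------------------------------------------------
# Persistence (single YAML document with fixed sections)
# --------------------------------------------------------------------------

_REQUIRED_SECTIONS = ("terms", "medications", "negation", "family",
                      "risk_rules", "stop_words")


def save_kb(kb: KnowledgeBase, path) -> None:
    doc = {
        "terms": [
            {"surface": t.surface, "source": t.source, "concept_group": t.concept_group}
            for t in kb.terms
        ],
        "medications": [
            {"name": m.name, "synonyms": sorted(m.synonyms)} for m in kb.medications
        ],
        "negation": sorted(kb.negation.triggers),
        "family": sorted(kb.family.triggers),
        "risk_rules": [
            {"factor": r.factor, "patterns": list(r.patterns),
             "value_map": {p: r.value_map[p] for p in r.patterns}}
            for r in kb.risk_rules
        ],
        "stop_words": sorted(kb.stop_words),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True),
                          encoding="utf-8")


def load_kb(path) -> KnowledgeBase:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: malformed lexicon file: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: lexicon file must be a mapping of sections")
    for section in _REQUIRED_SECTIONS:
        if section not in doc:
            raise ValueError(f"{path}: missing section {section!r}")
    try:
        terms = tuple(
            VocabularyTerm(surface=t["surface"], n_tokens=len(t["surface"].split()),
                           source=t.get("source", "custom"),
                           concept_group=t.get("concept_group", "dm_direct"))
            for t in doc["terms"]
        )
        meds = tuple(
            MedicationEntry(m["name"], frozenset(m.get("synonyms", ())))
            for m in doc["medications"]
        )
        rules = tuple(
            RiskFactorRule(r["factor"], tuple(r["patterns"]), dict(r["value_map"]))
            for r in doc["risk_rules"]
        )
        return KnowledgeBase(
            terms=terms,
            medications=meds,
            negation=TriggerLexicon("negation", frozenset(doc["negation"])),
            family=TriggerLexicon("family_history", frozenset(doc["family"])),
            risk_rules=rules,
            stop_words=frozenset(doc["stop_words"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid lexicon content: {exc}") from exc
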