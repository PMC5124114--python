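"""Feature extraction: map a cleaned note plus structured fields onto the
binary/categorical feature vector *f* and the codified-status flag.

Columns are: one binary indicator per controlled-vocabulary term, one per
medication, one-hot risk-factor categories, age (years) and one-hot sex.
The column order is fixed by the schema at training time and persisted with
the model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io import ClinicalNote
from .knowledge_base import (KnowledgeBase, RISK_FACTOR_CATEGORIES,
                             categorize_bmi, derive_bmi)
from .preprocess import preprocess_note

__all__ = ["FeatureSchema", "FeatureVector", "build_schema", "match_terms",
           "extract_risk_factors", "is_dm_codified", "vectorize",
           "vectorize_corpus"]

logger = logging.getLogger(__name__)

#: ICD-9-CM integer parts that codify a diabetes-mellitus diagnosis.
DM_ICD9_ROOTS = ("249", "250")

SEX_LEVELS = ("female", "male")


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed, ordered feature columns for the model."""

    term_features: tuple[str, ...]
    med_features: tuple[str, ...]
    risk_features: tuple[tuple[str, str], ...]  # (factor, category)
    demo_features: tuple[str, ...] = ("age",) + tuple(f"sex_{s}" for s in SEX_LEVELS)

    def __post_init__(self):
        cols = self.columns
        if len(cols) != len(set(cols)):
            raise ValueError("feature column names must be unique")

    @property
    def columns(self) -> list[str]:
        return ([f"term:{t}" for t in self.term_features]
                + [f"med:{m}" for m in self.med_features]
                + [f"risk:{f}={c}" for f, c in self.risk_features]
                + list(self.demo_features))

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    note_id: str
    codified: bool

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def build_schema(kb: KnowledgeBase) -> FeatureSchema:
    risk = tuple((rule.factor, cat)
                 for rule in kb.risk_rules
                 for cat in RISK_FACTOR_CATEGORIES[rule.factor])
    return FeatureSchema(
        term_features=tuple(kb.term_surfaces),
        med_features=tuple(kb.medication_names),
        risk_features=risk,
    )


@lru_cache(maxsize=8192)
def _phrase_pattern(phrase: str) -> re.Pattern:
    words = [re.escape(w) for w in phrase.split()]
    return re.compile(r"(?<![\w-])" + r"\s+".join(words) + r"(?![\w-])",
                      re.IGNORECASE)


def match_terms(cleaned_text: str, terms) -> np.ndarray:
    """Binary indicators: 1 iff the term occurs as a whole-word
    (phrase-contiguous) case-insensitive match in the cleaned text."""
    surfaces = [t if isinstance(t, str) else t.surface for t in terms]
    if not cleaned_text:
        return np.zeros(len(surfaces), dtype=float)
    return np.array([1.0 if _phrase_pattern(s).search(cleaned_text) else 0.0
                     for s in surfaces])


def _bmi_from_match(m: re.Match, sentinel: str) -> float | None:
    try:
        if sentinel == "@bmi":
            return float(m.group("value"))
        if sentinel == "@bmi_hw":
            return derive_bmi(float(m.group("height")), float(m.group("weight")),
                              height_unit=m.group("hunit"), weight_unit=m.group("wunit"))
    except (ValueError, ZeroDivisionError):
        return None
    return None


def extract_risk_factors(cleaned_text: str, rules) -> dict[str, str]:
    """First matching pattern per factor wins (rule pattern order is the
    precedence).  BMI is derived from height/weight when no explicit BMI is
    present; unusable matches are skipped, absent factors are simply missing
    from the mapping."""
    out: dict[str, str] = {}
    if not cleaned_text:
        return out
    for rule in rules:
        for pattern, value in rule.compiled():
            m = pattern.search(cleaned_text)
            if not m:
                continue
            if isinstance(value, str) and value.startswith("@"):
                if value in ("@bmi", "@bmi_hw"):
                    bmi = _bmi_from_match(m, value)
                    if bmi is None or not 5 <= bmi <= 120:
                        continue
                    category = categorize_bmi(bmi)
                elif value == "@bp":
                    if int(m.group("sys")) >= 140 or int(m.group("dia")) >= 90:
                        category = "present"
                    else:
                        continue
                else:  # pragma: no cover - guarded at rule construction
                    continue
            else:
                category = value
            if rule.factor in out and out[rule.factor] != category:
                logger.debug("risk factor %s: keeping first match %r over %r",
                             rule.factor, out[rule.factor], category)
            out.setdefault(rule.factor, category)
            break
    return out


def is_dm_codified(icd_codes) -> bool:
    """True iff any ICD-9-CM code has integer part 249 or 250.

    Dotted codes use the text before the first dot; undotted billing forms
    use the first three characters.  Unparseable codes are ignored.
    """
    for code in icd_codes or ():
        code = str(code).strip()
        if not code:
            continue
        root = code.split(".", 1)[0] if "." in code else code[:3]
        if root in DM_ICD9_ROOTS:
            return True
    return False


def vectorize(note: ClinicalNote, kb: KnowledgeBase, schema: FeatureSchema,
              demographics: dict | None = None, *, default_age: float = 50.0
              ) -> FeatureVector:
    """Deterministic composition: preprocess → term/medication matching +
    risk-factor extraction + demographics; the codified flag comes from the
    structured codes only."""
    cleaned = preprocess_note(note, kb)
    term_vals = match_terms(cleaned, schema.term_features)
    med_vals = match_terms(cleaned, schema.med_features)
    risks = extract_risk_factors(cleaned, kb.risk_rules)
    risk_vals = np.array([1.0 if risks.get(f) == c else 0.0
                          for f, c in schema.risk_features])

    demo = dict(demographics or {})
    age = demo.get("age", note.age)
    sex = (demo.get("sex", note.sex) or "unknown").lower()
    demo_vals = np.array([float(age) if age is not None else float(default_age)]
                         + [1.0 if sex == s else 0.0 for s in SEX_LEVELS])
    values = np.concatenate([term_vals, med_vals, risk_vals, demo_vals])
    return FeatureVector(values=values, note_id=note.note_id,
                         codified=is_dm_codified(note.icd_codes))


def vectorize_corpus(notes, kb: KnowledgeBase, schema: FeatureSchema | None = None,
                     *, default_age: float = 50.0):
    """Vectorize a corpus; returns (X, codified, note_ids, schema).

    ``X`` is float64 of shape (n_notes, len(schema)); missing ages are imputed
    with the corpus median age when available, else ``default_age``.
    """
    import pandas as pd

    notes = list(notes)
    if schema is None:
        schema = build_schema(kb)
    ages = [n.age for n in notes if n.age is not None]
    impute_age = float(np.median(ages)) if ages else default_age
    rows, codified, ids = [], [], []
    for note in notes:
        fv = vectorize(note, kb, schema, default_age=impute_age)
        rows.append(fv.values)
        codified.append(fv.codified)
        ids.append(note.note_id)
    X = np.vstack(rows) if rows else np.empty((0, len(schema)))
    frame = pd.DataFrame(X, columns=schema.columns, index=ids)
    return frame, np.asarray(codified, dtype=bool), ids, schema
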