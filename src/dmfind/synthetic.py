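"""Seeded synthetic clinical-note corpus with known ground truth.

The generator emulates the statistical structure a case-finding pipeline
must exploit — affirmative DM mentions, antidiabetic medication lists,
elevated risk-factor phrases, ICD-9-CM 249/250 codes on a configurable
fraction of true-DM patients, encounter dates permitting lead-time analysis
— and the confounds it must defeat: negated DM mentions ("Denies
diabetes."), family-history mentions ("Mother had diabetes mellitus."),
vitals lines exercising BMI/height-weight extraction, and decimal-point
sentence-boundary hazards.

Phrases come from a fixed template bank with slot filling: controllability
is deliberately chosen over realism.  Facilities are a categorical patient
attribute supporting train/blind-test facility splits.  All randomness flows
from a single seeded generator, so a fixed seed yields a byte-identical
serialized corpus.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .io import ClinicalNote

__all__ = ["GeneratorConfig", "GroundTruth", "generate_corpus",
           "make_gold_standard"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 5000
    prevalence: float = 0.10
    codified_fraction: float = 0.70
    negation_rate: float = 0.15
    family_history_rate: float = 0.10
    term_emission: dict = field(default_factory=lambda: {
        "dm_direct": 0.75, "complication": 0.25, "history": 0.35})
    med_emission: float = 0.50
    notes_per_patient_mean: float = 1.8   # 1 + Poisson(mean - 1)
    date_range: tuple = (dt.date(2013, 7, 1), dt.date(2014, 6, 30))
    icd_same_day_fraction: float = 0.6954
    icd_lag_mean_days: float = 48.0
    n_facilities: int = 8
    seed: int = 0

    def validate(self) -> None:
        probs = {"prevalence": self.prevalence,
                 "codified_fraction": self.codified_fraction,
                 "negation_rate": self.negation_rate,
                 "family_history_rate": self.family_history_rate,
                 "med_emission": self.med_emission,
                 "icd_same_day_fraction": self.icd_same_day_fraction,
                 **{f"term_emission[{k}]": v for k, v in self.term_emission.items()}}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        start, end = self.date_range
        if start > end:
            raise ValueError("date_range must be ordered (start <= end)")
        if self.n_facilities < 1:
            raise ValueError("n_facilities must be >= 1")
        if self.notes_per_patient_mean < 1:
            raise ValueError("notes_per_patient_mean must be >= 1")


class GroundTruth(dict):
    """patient_id -> {dm_status, first_dm_note_date, first_icd_date, facility_id}."""

    def dm_patients(self) -> list[str]:
        return [p for p, rec in self.items() if rec["dm_status"]]

    def to_records(self) -> dict:
        return dict(self)


# ---------------------------------------------------------------------------
# Template bank.  Affirmative DM templates must not contain negation or
# family-history trigger words; negated/family templates carry the DM mention
# only inside the trigger-bearing segment.
# ---------------------------------------------------------------------------

_FILLER = [
    "Patient seen today in clinic for routine follow up.",
    "Patient presents for evaluation of chronic back pain.",
    "Lungs clear to auscultation bilaterally.",
    "Heart regular rate and rhythm.",
    "Ambulating in hallway with steady gait.",
    "Reviewed laboratory results with patient.",
    "Plan discussed and patient agrees.",
    "Return to clinic in 3 months.",
    "Wound healing well at incision site.",
    "Patient reports improved energy since last visit.",
]

_DM_DIRECT = [
    "Assessment: diabetes mellitus type 2, continue current regimen.",
    "Patient carries a diagnosis of type 2 diabetes mellitus.",
    "Diabetes mellitus, poorly controlled, hba1c elevated at {a1c}.",
    "Known diabetic, blood sugar elevated this morning.",
    "Type 2 diabetes mellitus managed with diet and medication.",
    "Impression: uncontrolled diabetes with hyperglycemia.",
    "Diabetes mellitus type 1, insulin dependent.",
]

_DM_COMPLICATION = [
    "Funduscopic exam shows diabetic retinopathy.",
    "Monofilament testing consistent with diabetic neuropathy.",
    "Diabetic foot ulcer on left plantar surface, dressing changed.",
    "Urine studies suggest early diabetic nephropathy.",
]

_DM_HISTORY = [
    "History of diabetes mellitus, followed by endocrinology.",
    "Past medical history significant for diabetes.",
    "Known diabetic per prior records.",
]

_DM_NEGATED = [
    "Denies diabetes.",
    "Patient denied diabetes mellitus.",
    "Negative for diabetes mellitus.",
    "No history of diabetes.",
    "Diabetes ruled out after workup.",
]

_DM_FAMILY = [
    "Mother had diabetes mellitus.",
    "Father with type 2 diabetes.",
    "Family history of diabetes on maternal side.",
    "Sister has diabetes mellitus.",
]

_MEDS = ["metformin", "insulin", "glipizide", "glyburide", "glimepiride",
         "pioglitazone", "sitagliptin", "glargine", "liraglutide",
         "empagliflozin"]

_MED_TEMPLATES = [
    "Medications: {med} {dose} mg twice daily.",
    "Continue {med} {dose} mg daily.",
    "Started {med} {dose} mg with meals.",
]

_SMOKING = {"never": "Never smoker.",
            "former": "Former smoker, quit 5 years ago.",
            "current": "Current smoker, half pack per day."}

_ALCOHOL = {"use": "Drinks alcohol socially on weekends.",
            "disorder": "Alcohol use disorder, in counseling."}

_HTN = ["Hypertension, continues lisinopril.",
        "High blood pressure noted at triage."]

_NOTE_TYPES = ["progress note", "history and physical", "discharge summary",
               "emergency report"]


def _vitals_lines(rng, bmi: float, with_bp: bool, sys_: int, dia: int) -> list[str]:
    style = rng.integers(4)
    if style == 0:
        lines = [f"BMI {bmi:.1f}. Vital signs otherwise stable."]
    elif style == 1:
        lines = [f"BMI: {bmi:.1f}"]
    elif style == 2:
        h_m = rng.uniform(1.50, 1.95)
        w_kg = bmi * h_m * h_m
        lines = [f"Ht {h_m:.2f} m Wt {w_kg:.1f} kg"]
    else:
        h_cm = rng.uniform(150, 195)
        w_kg = bmi * (h_cm / 100) ** 2
        lines = [f"Height {h_cm:.0f} cm weight {w_kg:.1f} kg recorded today."]
    if with_bp:
        lines.append(f"BP {sys_}/{dia}.")
    return lines


def _pick(rng, bank):
    return bank[int(rng.integers(len(bank)))]


def generate_corpus(config: GeneratorConfig
                    ) -> tuple[list[ClinicalNote], GroundTruth]:
    """Generate a seeded corpus and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    start, end = config.date_range
    n_days = (end - start).days + 1

    notes: list[ClinicalNote] = []
    truth = GroundTruth()

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        facility = f"F{int(rng.integers(config.n_facilities))}"
        dm = bool(rng.random() < config.prevalence)
        sex = "female" if rng.random() < 0.5 else "male"
        age = float(np.clip(rng.normal(66, 10) if dm else rng.normal(48, 16),
                            18, 95))
        k = 1 + int(rng.poisson(max(config.notes_per_patient_mean - 1, 0.0)))
        day_offsets = np.sort(rng.choice(n_days, size=k, replace=False)
                              if k <= n_days else rng.integers(0, n_days, size=k))
        dates = [start + dt.timedelta(days=int(d)) for d in day_offsets]

        def build_note_text(force_dm_mention=False):
            """One note's text; returns (text, mentions_dm)."""
            sentences = [_pick(rng, _FILLER)]
            mentions_dm = False
            # vitals with a decimal hazard; DM patients skew obese/hypertensive
            if rng.random() < 0.8:
                bmi = float(np.clip(rng.normal(33, 4) if dm else rng.normal(26, 4),
                                    17, 48))
                with_bp = rng.random() < (0.45 if dm else 0.15)
                sys_ = int(rng.integers(142, 180)) if with_bp else int(rng.integers(105, 135))
                dia = int(rng.integers(90, 110)) if with_bp else int(rng.integers(60, 85))
                sentences += _vitals_lines(rng, bmi, with_bp, sys_, dia)
                if with_bp and rng.random() < 0.5:
                    sentences.append(_pick(rng, _HTN))
            if rng.random() < 0.5:
                weights = ([0.35, 0.35, 0.30] if dm else [0.20, 0.30, 0.50])
                status = rng.choice(["current", "former", "never"], p=weights)
                sentences.append(_SMOKING[str(status)])
            if rng.random() < 0.3:
                kind = "disorder" if rng.random() < (0.3 if dm else 0.1) else "use"
                sentences.append(_ALCOHOL[kind])
            if dm:
                if force_dm_mention or \
                        rng.random() < config.term_emission.get("dm_direct", 0.0):
                    sentences.append(_pick(rng, _DM_DIRECT).format(
                        a1c=f"{rng.uniform(7.5, 12.0):.1f}"))
                    mentions_dm = True
                if rng.random() < config.term_emission.get("complication", 0.0):
                    sentences.append(_pick(rng, _DM_COMPLICATION))
                    mentions_dm = True
                if rng.random() < config.term_emission.get("history", 0.0):
                    sentences.append(_pick(rng, _DM_HISTORY))
                    mentions_dm = True
                if rng.random() < config.med_emission:
                    for med in rng.choice(_MEDS, size=int(rng.integers(1, 3)),
                                          replace=False):
                        sentences.append(_pick(rng, _MED_TEMPLATES).format(
                            med=med, dose=int(rng.choice([250, 500, 850, 1000]))))
            else:
                if rng.random() < config.negation_rate:
                    sentences.append(_pick(rng, _DM_NEGATED))
            if rng.random() < config.family_history_rate:
                sentences.append(_pick(rng, _DM_FAMILY))
            sentences.append(_pick(rng, _FILLER))

            # assemble: vitals-style short lines go on their own line, the
            # rest flows into sentence-joined paragraphs
            parts, para = [], []
            for s in sentences:
                if s.endswith((".", "!", "?")):
                    para.append(s)
                else:
                    if para:
                        parts.append(" ".join(para))
                        para = []
                    parts.append(s)
            if para:
                parts.append(" ".join(para))
            sep = "\n" if rng.random() < 0.5 else "\n\n"
            return sep.join(parts), mentions_dm

        note_texts, dm_mention_flags = [], []
        for j in range(k):
            text_j, mentions_j = build_note_text()
            note_texts.append(text_j)
            dm_mention_flags.append(mentions_j)

        # ICD assignment: a codified_fraction of DM patients carry 249/250
        # codes, lagging the first DM-text note by 0 days (same encounter)
        # or a geometric-tailed positive lag; a positive lag creates the
        # coding encounter itself — a full clinical note that documents the
        # diagnosis being coded (a code on a content-free note would teach
        # the model that empty text implies DM)
        first_text_date = None
        anchor_idx = 0
        for j, flag in enumerate(dm_mention_flags):
            if flag:
                first_text_date = dates[j]
                anchor_idx = j
                break
        icd_by_note = [[] for _ in range(k)]
        first_icd_date = None
        coding_note = None
        if dm and rng.random() < config.codified_fraction:
            if rng.random() < config.icd_same_day_fraction or config.icd_lag_mean_days <= 1:
                lag = 0
            else:
                lag = int(rng.geometric(1.0 / config.icd_lag_mean_days))
            anchor = first_text_date if first_text_date is not None else dates[0]
            code = str(rng.choice(["250.00", "250.0", "250.02", "2500", "249.00"]))
            if lag == 0:
                icd_by_note[anchor_idx].append(code)
                first_icd_date = anchor
            else:
                first_icd_date = min(anchor + dt.timedelta(days=lag), end)
                coding_note = (first_icd_date, code)
            for j in range(k):
                if dates[j] > first_icd_date and rng.random() < 0.5:
                    icd_by_note[j].append("250.00")
        # non-DM structured codes (never 249/250)
        for j in range(k):
            if rng.random() < 0.4:
                icd_by_note[j].append(str(rng.choice(["401.9", "272.4", "530.81",
                                                      "719.46", "V58.67"])))

        for j in range(k):
            notes.append(ClinicalNote(
                note_id=f"{pid}-N{j:02d}",
                patient_id=pid,
                encounter_date=dates[j],
                facility_id=facility,
                note_type=_pick(rng, _NOTE_TYPES),
                text=note_texts[j],
                icd_codes=tuple(icd_by_note[j]),
                age=round(age, 1),
                sex=sex,
            ))
        if coding_note is not None:
            code_date, code = coding_note
            coding_text, coding_mentions = build_note_text(force_dm_mention=True)
            notes.append(ClinicalNote(
                note_id=f"{pid}-N{k:02d}",
                patient_id=pid,
                encounter_date=code_date,
                facility_id=facility,
                note_type="progress note",
                text=coding_text,
                icd_codes=(code,),
                age=round(age, 1),
                sex=sex,
            ))
            if first_text_date is None and coding_mentions:
                first_text_date = code_date
        truth[pid] = {
            "dm_status": dm,
            "first_dm_note_date": first_text_date,
            "first_icd_date": first_icd_date,
            "facility_id": facility,
        }
    return notes, truth


def make_gold_standard(corpus, truth: GroundTruth, n_pos: int, n_neg: int,
                       seed: int = 0, *, patient_ids=None) -> "pd.DataFrame":
    """Seeded stratified patient sample with exact class counts (stands in
    for a chart-review-adjudicated gold standard).  ``patient_ids`` restricts
    the sampling frame (e.g. to the training facilities)."""
    import pandas as pd

    frame = sorted(patient_ids) if patient_ids is not None else sorted(truth)
    pos = [p for p in frame if truth[p]["dm_status"]]
    neg = [p for p in frame if not truth[p]["dm_status"]]
    if len(pos) < n_pos or len(neg) < n_neg:
        raise ValueError(
            f"insufficient class size: have {len(pos)} DM / {len(neg)} non-DM, "
            f"requested {n_pos}/{n_neg}")
    rng = np.random.default_rng(seed)
    sel_pos = [pos[i] for i in np.sort(rng.choice(len(pos), n_pos, replace=False))]
    sel_neg = [neg[i] for i in np.sort(rng.choice(len(neg), n_neg, replace=False))]
    return pd.DataFrame({
        "patient_id": sel_pos + sel_neg,
        "dm_status": [True] * n_pos + [False] * n_neg,
    })
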