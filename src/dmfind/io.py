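"""Clinical-note records and line-delimited corpus I/O.

A corpus is a JSON-lines file, one note per line, with the fields of
:class:`ClinicalNote`.  Ground-truth files (one patient per line) carry the
adjudicated DM status and the dates needed for lead-time analysis.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class ClinicalNote:
    """One encounter-based free-text note with its structured codes.

    ``icd_codes`` are ICD-9-CM diagnosis codes attached to the encounter
    (dotted or undotted billing form).  ``age``/``sex`` are structured
    demographics of the patient at the encounter; either may be missing.
    """

    note_id: str
    patient_id: str
    encounter_date: dt.date
    facility_id: str
    note_type: str
    text: str
    icd_codes: tuple[str, ...] = field(default_factory=tuple)
    age: float | None = None
    sex: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "encounter_date", _parse_date(self.encounter_date))
        object.__setattr__(self, "icd_codes", tuple(self.icd_codes))

    def to_record(self) -> dict:
        rec = asdict(self)
        rec["encounter_date"] = self.encounter_date.isoformat()
        rec["icd_codes"] = list(self.icd_codes)
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "ClinicalNote":
        return cls(
            note_id=str(rec["note_id"]),
            patient_id=str(rec["patient_id"]),
            encounter_date=_parse_date(rec["encounter_date"]),
            facility_id=str(rec.get("facility_id", "")),
            note_type=str(rec.get("note_type", "")),
            text=rec.get("text", "") or "",
            icd_codes=tuple(rec.get("icd_codes", ()) or ()),
            age=rec.get("age"),
            sex=rec.get("sex"),
        )


def write_notes(notes: Iterable[ClinicalNote], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps(note.to_record(), sort_keys=True) + "\n")


def read_notes(path) -> list[ClinicalNote]:
    path = Path(path)
    notes = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                notes.append(ClinicalNote.from_record(json.loads(line)))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed note record: {exc}") from exc
    return notes


def iter_notes(path) -> Iterator[ClinicalNote]:
    yield from read_notes(path)


def write_truth(truth: dict, path) -> None:
    """Write per-patient ground truth (see synthetic.GroundTruth.to_records)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for pid in sorted(truth):
            entry = dict(truth[pid])
            entry["patient_id"] = pid
            for key in ("first_dm_note_date", "first_icd_date"):
                if entry.get(key) is not None:
                    entry[key] = entry[key].isoformat() if isinstance(entry[key], dt.date) else str(entry[key])
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    path = Path(path)
    truth = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                pid = str(rec.pop("patient_id"))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed truth record: {exc}") from exc
            for key in ("first_dm_note_date", "first_icd_date"):
                if rec.get(key) is not None:
                    rec[key] = _parse_date(rec[key])
            truth[pid] = rec
    return truth
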