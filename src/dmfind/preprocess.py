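"""Note preprocessing: decompose free text into basic units and drop units
carrying negation or family-history triggers.

A note is collapsed into paragraphs, sentences, and lines as non-overlapping
basic units.  Negation scope is the whole unit: if a unit contains any
trigger phrase as a whole-word, case-insensitive match, the unit is removed
before feature matching.  This segment-scope rule (rather than a token
window) is deliberately conservative — it trades a little recall of
affirmative mentions that share a sentence with a negation for high
specificity of what survives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from .knowledge_base import KnowledgeBase, TriggerLexicon

__all__ = ["Segment", "segment_note", "filter_segments", "preprocess_note",
           "trigger_pattern"]

# Sentence boundary: terminal punctuation, whitespace, then an uppercase
# letter, digit or opening quote/paren.  A decimal point never matches (no
# whitespace between the digits), and a short abbreviation list is protected.
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[\"'(\[]?[A-Z0-9])")
_ABBREVIATIONS = {"dr", "mr", "mrs", "ms", "vs", "st", "jr", "sr", "prof",
                  "no", "e.g", "i.e", "etc"}

#: Paragraphs at most this long with no internal sentence boundary are kept
#: as a single unit.
MAX_WHOLE_PARAGRAPH_CHARS = 200


@dataclass(frozen=True)
class Segment:
    """A basic unit of note text with its character span (0-based, half-open)."""

    text: str
    span: tuple[int, int]
    unit: str  # "paragraph" | "sentence" | "line"


def _word_before(text: str, idx: int) -> str:
    m = re.search(r"[\w.]+$", text[:idx])
    return m.group(0).lower().rstrip(".") if m else ""


def _sentence_spans(text: str, start: int, end: int) -> list[tuple[int, int]]:
    """Split text[start:end] at sentence boundaries; returns absolute spans."""
    spans = []
    seg_start = start
    for m in _BOUNDARY_RE.finditer(text, start, end):
        if _word_before(text, m.start()) in _ABBREVIATIONS:
            continue
        cut = m.end()
        spans.append((seg_start, cut))
        seg_start = cut
    if seg_start < end:
        spans.append((seg_start, end))
    return spans


def _trimmed(text: str, lo: int, hi: int) -> tuple[int, int] | None:
    while lo < hi and text[lo].isspace():
        lo += 1
    while hi > lo and text[hi - 1].isspace():
        hi -= 1
    return (lo, hi) if hi > lo else None


def segment_note(text: str, *, max_whole_paragraph: int = MAX_WHOLE_PARAGRAPH_CHARS
                 ) -> list[Segment]:
    """Decompose note text into ordered, non-overlapping basic units.

    Paragraphs are separated by blank lines.  A single-line paragraph short
    enough (≤ ``max_whole_paragraph`` chars) with no internal sentence
    boundary is one ``paragraph`` unit; multi-line paragraphs are treated
    line-wise (template blocks like ``BMI: 31`` stay whole as ``line``
    units); anything with detected sentence boundaries is sentence-split.
    """
    if not text or text.isspace():
        return []
    segments: list[Segment] = []
    # paragraph spans: split on runs of newline containing at least one blank line
    para_bounds = []
    pos = 0
    for m in re.finditer(r"\n[ \t]*\n+", text):
        para_bounds.append((pos, m.start()))
        pos = m.end()
    para_bounds.append((pos, len(text)))

    for plo, phi in para_bounds:
        trimmed = _trimmed(text, plo, phi)
        if trimmed is None:
            continue
        plo, phi = trimmed
        para = text[plo:phi]
        multi_line = "\n" in para
        line_bounds = []
        lpos = plo
        if multi_line:
            for m in re.finditer(r"\n", text[plo:phi]):
                line_bounds.append((lpos, plo + m.start()))
                lpos = plo + m.end()
        line_bounds.append((lpos, phi))

        for llo, lhi in line_bounds:
            lt = _trimmed(text, llo, lhi)
            if lt is None:
                continue
            llo, lhi = lt
            sspans = _sentence_spans(text, llo, lhi)
            if len(sspans) == 1:
                if multi_line:
                    unit = "line"
                elif lhi - llo <= max_whole_paragraph:
                    unit = "paragraph"
                else:
                    unit = "sentence"
                segments.append(Segment(text[llo:lhi], (llo, lhi), unit))
            else:
                for slo, shi in sspans:
                    st = _trimmed(text, slo, shi)
                    if st is None:
                        continue
                    slo, shi = st
                    segments.append(Segment(text[slo:shi], (slo, shi), "sentence"))
    return segments


@lru_cache(maxsize=64)
def _compiled_trigger_pattern(triggers: frozenset[str]) -> re.Pattern:
    # longest-first so multi-word phrases win over their own prefixes
    parts = sorted(triggers, key=len, reverse=True)
    alts = [re.escape(t).replace(r"\ ", r"\s+") for t in parts]
    return re.compile(r"(?<![\w-])(?:" + "|".join(alts) + r")(?![\w-])",
                      re.IGNORECASE)


def trigger_pattern(lexicon: TriggerLexicon) -> re.Pattern:
    """Whole-word, case-insensitive alternation over the lexicon's triggers."""
    return _compiled_trigger_pattern(lexicon.triggers)


def filter_segments(segments: list[Segment], negation: TriggerLexicon,
                    family: TriggerLexicon) -> list[Segment]:
    """Drop every segment containing a negation or family-history trigger.

    Whole-word, case-insensitive matching; multi-word triggers match as
    contiguous phrases.  The output is an order-preserving subsequence of the
    input with segments unchanged.
    """
    neg = trigger_pattern(negation)
    fam = trigger_pattern(family)
    return [s for s in segments
            if not neg.search(s.text) and not fam.search(s.text)]


def preprocess_note(note_or_text, kb: KnowledgeBase) -> str:
    """Segment, remove negated/family-history units, and rejoin with newlines."""
    text = note_or_text if isinstance(note_or_text, str) else note_or_text.text
    kept = filter_segments(segment_note(text), kb.negation, kb.family)
    return "\n".join(s.text for s in kept)
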