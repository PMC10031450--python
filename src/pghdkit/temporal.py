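"""Detection and normalization of date/time expressions in notes.

Diary-style notes mostly carry *relative* dates ("yesterday", "2 days
ago") and clock times ("at 6:00 am"); both are resolved against the
note's authorship date, which is injected explicitly so resolution is a
pure function with no wall-clock dependence.  Phrasal referents without
a numeric anchor ("a few days ago") are detected but deliberately left
unresolved — guessing an offset would fabricate data — and surface in
the output with status ``unresolved_phrasal``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
import datetime as dt
from datetime import timedelta
from typing import List, Optional

from pydantic import BaseModel, model_validator

from pghdkit.lexicon import Lexicon
from pghdkit.parsing import ParsedSentence

MONTHS = {
    name: i + 1
    for i, name in enumerate(
        "january february march april may june july august september october november december".split()
    )
}
MONTHS.update({name[:3]: num for name, num in list(MONTHS.items())})

# am/pm abbreviation: "am", "a.m." — but never swallow a bare sentence period
_CLOCK_RE = re.compile(r"\b(\d{1,2}):(\d{2})(?:\s*([ap])(?:\.m\.|m\b))?(?!\d)", re.IGNORECASE)
_NDAYS_RE = re.compile(r"\b(\d+)\s+(day|week)s?\s+ago\b", re.IGNORECASE)
_MONTHNAME_RE = re.compile(
    r"\b(" + "|".join(sorted(MONTHS, key=len, reverse=True)) + r")\.?\s+(\d{1,2})(?:st|nd|rd|th)?(?:,?\s*(\d{4}))?\b",
    re.IGNORECASE,
)
_NUMERIC_DATE_RE = re.compile(r"\b(\d{1,2})/(\d{1,2})(?:/(\d{2,4}))?\b")


class SpanKind(str, enum.Enum):
    clock = "clock"
    absolute_date = "absolute_date"
    relative = "relative"
    phrasal = "phrasal"


@dataclass(frozen=True)
class TemporalSpan:
    start: int
    end: int
    text: str
    kind: SpanKind
    code: str  # semantic payload: e.g. "D-1", "PHRASAL", or the raw match


class WhenStatus(str, enum.Enum):
    resolved = "resolved"
    unresolved_phrasal = "unresolved_phrasal"


class ResolvedWhen(BaseModel):
    """A normalized date and/or time-of-day for a medication instance.

    ``provenance`` records where the date came from: ``explicit`` (stated
    in the same sentence), ``inherited`` (nearest preceding resolved date
    in the note), or ``note-date-default`` (authorship date fallback).
    ``meridiem_ambiguous`` marks clock times written without am/pm.
    """

    raw: str
    date: Optional[dt.date] = None
    time_of_day: Optional[dt.time] = None
    status: WhenStatus = WhenStatus.resolved
    provenance: str = "explicit"
    meridiem_ambiguous: bool = False

    @model_validator(mode="after")
    def _status_consistency(self) -> "ResolvedWhen":
        if self.status == WhenStatus.resolved:
            if self.date is None and self.time_of_day is None:
                raise ValueError("resolved ResolvedWhen needs a date or a time")
        else:
            if self.date is not None or self.time_of_day is not None:
                raise ValueError("unresolved_phrasal ResolvedWhen must carry no date/time")
        return self


def detect_temporal(
    sentence: ParsedSentence, text: str, trigger_lexicon: Optional[Lexicon] = None
) -> List[TemporalSpan]:
    """Find clock times, absolute dates, and relative/phrasal triggers.

    Overlapping candidates are resolved longest-first (then leftmost), so
    "a few days ago" shadows its "few days ago" suffix and "3 days ago"
    is one relative span, not a bare number.
    """
    seg = text[sentence.sent_start : sentence.sent_end]
    off = sentence.sent_start
    candidates: List[TemporalSpan] = []

    for m in _CLOCK_RE.finditer(seg):
        hh = int(m.group(1))
        if hh > 23:
            continue
        candidates.append(
            TemporalSpan(m.start() + off, m.end() + off, m.group(0), SpanKind.clock, m.group(0))
        )
    for m in _NDAYS_RE.finditer(seg):
        n = int(m.group(1))
        days = n * 7 if m.group(2).lower().startswith("week") else n
        candidates.append(
            TemporalSpan(m.start() + off, m.end() + off, m.group(0), SpanKind.relative, f"D-{days}")
        )
    for m in _MONTHNAME_RE.finditer(seg):
        candidates.append(
            TemporalSpan(
                m.start() + off, m.end() + off, m.group(0), SpanKind.absolute_date, m.group(0)
            )
        )
    for m in _NUMERIC_DATE_RE.finditer(seg):
        candidates.append(
            TemporalSpan(
                m.start() + off, m.end() + off, m.group(0), SpanKind.absolute_date, m.group(0)
            )
        )
    if trigger_lexicon is not None:
        for term, (code, _cid) in trigger_lexicon.entries.items():
            for m in re.finditer(r"\b" + re.escape(term) + r"\b", seg, re.IGNORECASE):
                kind = SpanKind.phrasal if code == "PHRASAL" else SpanKind.relative
                candidates.append(
                    TemporalSpan(m.start() + off, m.end() + off, m.group(0), kind, code)
                )

    # longest-first, then leftmost; drop overlaps with already-kept spans
    chosen: List[TemporalSpan] = []
    for cand in sorted(candidates, key=lambda s: (-(s.end - s.start), s.start)):
        if all(cand.end <= k.start or cand.start >= k.end for k in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda s: s.start)
    return chosen


def _resolve_clock(raw: str) -> ResolvedWhen:
    m = _CLOCK_RE.search(raw)
    assert m is not None
    hh, mm = int(m.group(1)), int(m.group(2))
    meridiem = m.group(3)
    ambiguous = meridiem is None
    if meridiem is not None:
        meridiem = meridiem.lower()
        if meridiem == "p" and hh != 12:
            hh += 12
        elif meridiem == "a" and hh == 12:
            hh = 0
    return ResolvedWhen(
        raw=raw, time_of_day=dt.time(hh % 24, mm), meridiem_ambiguous=ambiguous
    )


def _resolve_absolute(raw: str, reference: dt.date, dialect: str) -> Optional[ResolvedWhen]:
    m = _MONTHNAME_RE.search(raw)
    if m:
        month = MONTHS[m.group(1).lower()]
        day = int(m.group(2))
        year = int(m.group(3)) if m.group(3) else reference.year
        try:
            return ResolvedWhen(raw=raw, date=dt.date(year, month, day))
        except ValueError:
            return None
    m = _NUMERIC_DATE_RE.search(raw)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        year = int(m.group(3)) if m.group(3) else reference.year
        if year < 100:
            year += 2000
        month, day = (a, b) if dialect == "mdy" else (b, a)
        try:
            return ResolvedWhen(raw=raw, date=dt.date(year, month, day))
        except ValueError:
            return None
    return None


def resolve(span: TemporalSpan, reference: dt.date, dialect: str = "mdy") -> Optional[ResolvedWhen]:
    """Resolve a detected span against the note's authorship date.

    Returns None only for syntactically detected but semantically invalid
    absolute dates (e.g. "25/25"); phrasal referents return a
    ``ResolvedWhen`` with status ``unresolved_phrasal``.
    """
    if span.kind == SpanKind.clock:
        return _resolve_clock(span.text)
    if span.kind == SpanKind.phrasal:
        return ResolvedWhen(raw=span.text, status=WhenStatus.unresolved_phrasal)
    if span.kind == SpanKind.relative:
        offset = int(span.code[1:])  # "D-1" -> -1, "D0" -> 0
        return ResolvedWhen(raw=span.text, date=reference + timedelta(days=offset))
    return _resolve_absolute(span.text, reference, dialect)
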