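"""Core data model for notes and extraction results, with JSONL I/O.

Notes are exchanged as JSON Lines: one object per line with keys
``note_id``, ``text``, ``authored_at`` (ISO-8601), ``modality``
(``voice_transcript`` | ``typed``) and optional ``author_id``.  Unknown
extra keys are preserved on read and echoed on write, so the format is
forward compatible.  All character offsets used downstream are 0-based,
half-open ``[start, end)`` over Unicode code points.
"""

from __future__ import annotations

import enum
import json
import logging
from datetime import date, datetime
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, List, Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from pghdkit.extract import MedicationInstance, SymptomMention

logger = logging.getLogger(__name__)


class Modality(str, enum.Enum):
    voice_transcript = "voice_transcript"
    typed = "typed"


class NoteCategory(str, enum.Enum):
    """Information categories of a note (medication and/or symptom content)."""

    medication_only = "medication_only"
    symptom_only = "symptom_only"
    both = "both"
    none = "none"


class Note(BaseModel):
    """One free-text patient/caregiver note entry.

    ``authored_at`` is the authorship timestamp; relative temporal
    expressions inside the text ("yesterday", "2 days ago") are resolved
    against its calendar date.
    """

    model_config = ConfigDict(extra="allow")

    note_id: str
    text: str
    authored_at: datetime
    modality: Modality = Modality.typed
    author_id: Optional[str] = None

    @field_validator("text")
    @classmethod
    def _non_empty_text(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("note text must be non-empty")
        return v

    @property
    def reference_date(self) -> date:
        return self.authored_at.date()


class ExtractionResult(BaseModel):
    """Everything the pipeline extracted from one note.

    Instance and mention lists preserve text order (by start offset of the
    anchoring entity); ``category`` is a pure function of list emptiness.
    """

    note_id: str
    medication_instances: List["MedicationInstance"] = []
    symptom_mentions: List["SymptomMention"] = []
    category: NoteCategory = NoteCategory.none


def categorize(result: ExtractionResult) -> NoteCategory:
    """Classify a note by whether it carries medication and/or symptom info."""
    has_med = bool(result.medication_instances)
    has_sym = bool(result.symptom_mentions)
    if has_med and has_sym:
        return NoteCategory.both
    if has_med:
        return NoteCategory.medication_only
    if has_sym:
        return NoteCategory.symptom_only
    return NoteCategory.none


def read_notes(path: Union[str, Path]) -> List[Note]:
    """Read a JSONL notes file, skipping (and logging) malformed lines.

    Raises ``ValueError`` if the file yields no valid note at all.
    """
    path = Path(path)
    notes: List[Note] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                logger.warning("%s:%d: skipping malformed JSON line (%s)", path, lineno, exc)
                continue
            try:
                notes.append(Note.model_validate(obj))
            except Exception as exc:
                logger.warning("%s:%d: skipping invalid note record (%s)", path, lineno, exc)
    if not notes:
        raise ValueError(f"no valid notes found in {path}")
    return notes


def write_notes(notes: Iterable[Note], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(note.model_dump_json() + "\n")


def write_extractions(results: Iterable[ExtractionResult], path: Union[str, Path]) -> None:
    """Write extraction results as JSONL, one object per note, in order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for result in results:
            fh.write(result.model_dump_json() + "\n")


def read_extractions(path: Union[str, Path]) -> List[ExtractionResult]:
    """Inverse of :func:`write_extractions` (strict: malformed lines raise)."""
    path = Path(path)
    results: List[ExtractionResult] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                results.append(ExtractionResult.model_validate_json(line))
    return results


def _rebuild_models() -> None:
    # ExtractionResult references extract-module types via forward refs.
    from pghdkit import extract  # noqa: F401

    ExtractionResult.model_rebuild(
        _types_namespace={
            "MedicationInstance": extract.MedicationInstance,
            "SymptomMention": extract.SymptomMention,
        }
    )
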