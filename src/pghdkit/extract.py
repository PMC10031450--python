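"""Assembly of medication instances and symptom mentions from parsed notes.

This is the heart of the pipeline.  After dictionary NER locates
medication, symptom, and unit mentions, two dependency/POS rules collect
quantity-unit pairs inside each sentence:

Q1  a NUM token whose ``nummod`` head is a unit-lexicon token yields
    (quantity, unit) — "a rate of 2.6 ml";
Q2  a NUM token whose head is (or that immediately precedes) the head
    token of a medication mention yields (quantity, no unit) —
    "2 Benadryl".

Each NUM is consumed at most once (Q1 wins); clock-time tokens are
reserved for temporal extraction and never become quantities.  Pairs
attach to the medication mention with the shortest dependency-path
distance (ties: character distance, then leftmost), one instance per
pair, so a dose taper enumerated in one sentence yields one instance per
rate in text order.  Quantity/unit search never crosses a sentence
boundary: information split between sentences is a known failure mode of
this family of pipelines and the rules stay faithful to it.

Negation is not modelled: "no fever" still yields a fever mention with
polarity "asserted".
"""

from __future__ import annotations

import logging
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, field_validator, model_validator

from pghdkit.corpus import ExtractionResult, Note, categorize, _rebuild_models
from pghdkit.lexicon import (
    EntityMention,
    Lexicon,
    Vocabulary,
    load_lexicon_dir,
    match_entities,
    normalize_term,
)
from pghdkit.parsing import CLOCK_RE, Backend, ParsedSentence, analyze, get_backend
from pghdkit.temporal import (
    ResolvedWhen,
    SpanKind,
    WhenStatus,
    detect_temporal,
    resolve,
)

logger = logging.getLogger(__name__)


class MedicationInstance(BaseModel):
    """One medication event: name plus whichever of quantity, unit, and
    date/time were stated.  The medication mention is the anchor; a unit
    never appears without its quantity, and quantities are positive."""

    medication: EntityMention
    quantity: Optional[float] = None
    unit: Optional[EntityMention] = None
    when: Optional[ResolvedWhen] = None
    evidence_sentence: int = 0

    @field_validator("quantity")
    @classmethod
    def _positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("quantity must be > 0")
        return v

    @model_validator(mode="after")
    def _unit_needs_quantity(self) -> "MedicationInstance":
        if self.unit is not None and self.quantity is None:
            raise ValueError("a unit never floats without a quantity")
        return self


class SymptomMention(BaseModel):
    """A symptom occurrence; polarity is always "asserted" (no negation)."""

    symptom: EntityMention
    polarity: Literal["asserted"] = "asserted"
    evidence_sentence: int = 0


_rebuild_models()


def parse_quantity(surface: str) -> Optional[float]:
    """Numeric value of a NUM token; a range like "1-2" takes the first number."""
    if CLOCK_RE.match(surface):
        return None
    head = surface.split("-")[0]
    try:
        value = float(head)
    except ValueError:
        return None
    return value if value > 0 else None


def find_quantity_unit_pairs(
    sentence: ParsedSentence,
    unit_lexicon: Lexicon,
    medication_head_indices: Sequence[int] = (),
) -> List[Tuple[int, Optional[int]]]:
    """Apply rules Q1/Q2; returns (NUM token index, unit token index or None).

    Pairs are ordered by text position and each NUM token is used at most
    once, with Q1 taking precedence over Q2.
    """
    toks = list(sentence.tokens)
    unit_terms = set(unit_lexicon.entries)
    med_heads = set(medication_head_indices)
    used: set = set()
    pairs: List[Tuple[int, Optional[int]]] = []

    def is_quantity_num(t) -> bool:
        return t.pos == "NUM" and not CLOCK_RE.match(t.surface)

    for t in toks:  # Q1
        if not is_quantity_num(t) or t.index in used:
            continue
        head = toks[t.head]
        if (
            t.dep_label == "nummod"
            and head.index != t.index
            and normalize_term(head.surface) in unit_terms
        ):
            pairs.append((t.index, head.index))
            used.add(t.index)
    for t in toks:  # Q2
        if not is_quantity_num(t) or t.index in used:
            continue
        if t.head in med_heads or (t.index + 1 in med_heads):
            pairs.append((t.index, None))
            used.add(t.index)
    pairs.sort(key=lambda p: toks[p[0]].start)
    return pairs


def _path_to_root(toks, i: int) -> List[int]:
    path = [i]
    while toks[i].head != i:
        i = toks[i].head
        path.append(i)
    return path


def dependency_distance(sentence: ParsedSentence, a: int, b: int) -> int:
    """Length of the undirected tree path between two token indices."""
    toks = list(sentence.tokens)
    pa, pb = _path_to_root(toks, a), _path_to_root(toks, b)
    depth = {node: d for d, node in enumerate(pa)}
    for d, node in enumerate(pb):
        if node in depth:
            return depth[node] + d
    return len(pa) + len(pb)  # unreachable for a valid tree


def attach_to_medication(
    pairs: List[Tuple[int, Optional[int]]],
    medications: List[EntityMention],
    sentence: ParsedSentence,
    unit_lexicon: Lexicon,
) -> List[MedicationInstance]:
    """Attach quantity(-unit) pairs to medication mentions of one sentence.

    Each pair goes to the medication whose head token is closest along
    the dependency path (ties: character distance, then leftmost).  A
    medication with no pair still yields one bare instance; a medication
    with k pairs yields k instances in text order.
    """
    if not medications:
        return []
    toks = list(sentence.tokens)
    attached: Dict[int, List[Tuple[int, Optional[int]]]] = {i: [] for i in range(len(medications))}
    for num_idx, unit_idx in pairs:
        num_tok = toks[num_idx]

        def sort_key(item):
            m_i, med = item
            return (
                dependency_distance(sentence, num_idx, med.head_token_index),
                abs(num_tok.start - med.start),
                med.start,
            )

        best_i, _best = min(enumerate(medications), key=sort_key)
        attached[best_i].append((num_idx, unit_idx))

    instances: List[MedicationInstance] = []
    for m_i, med in enumerate(medications):
        med_pairs = sorted(attached[m_i], key=lambda p: toks[p[0]].start)
        if not med_pairs:
            instances.append(MedicationInstance(medication=med))
            continue
        for num_idx, unit_idx in med_pairs:
            quantity = parse_quantity(toks[num_idx].surface)
            if quantity is None:
                instances.append(MedicationInstance(medication=med))
                continue
            if unit_idx is not None:
                ut = toks[unit_idx]
                instances.append(
                    MedicationInstance(
                        medication=med,
                        quantity=quantity,
                        unit=_unit_mention(ut, med.sentence_index, unit_lexicon),
                    )
                )
            else:
                instances.append(MedicationInstance(medication=med, quantity=quantity))
    instances.sort(key=lambda inst: inst.medication.start)
    return instances


def _unit_mention(tok, sentence_index: int, unit_lexicon: Lexicon) -> EntityMention:
    # Build an EntityMention for a unit token identified structurally.
    canonical, concept_id = unit_lexicon.entries[normalize_term(tok.surface)]
    return EntityMention(
        start=tok.start,
        end=tok.end,
        surface=tok.surface,
        vocabulary=Vocabulary.unit,
        concept_id=concept_id,
        canonical=canonical,
        sentence_index=sentence_index,
        head_token_index=tok.index,
    )


def extract_symptoms(mentions: List[EntityMention]) -> List[SymptomMention]:
    """One SymptomMention per symptom entity mention — every occurrence
    counts; repeats across sentences are not deduplicated."""
    return [
        SymptomMention(symptom=m, evidence_sentence=m.sentence_index)
        for m in sorted(mentions, key=lambda m: m.start)
    ]


def _sentence_when(
    spans: List,
    reference,
    dialect: str,
    last_date: Optional[ResolvedWhen],
) -> Tuple[Optional[ResolvedWhen], Optional[ResolvedWhen]]:
    """Combine a sentence's temporal spans into one ResolvedWhen.

    Returns (when for this sentence's instances, updated last explicit
    date).  Precedence: an explicit resolvable date wins; otherwise a
    phrasal referent leaves the instance unresolved; otherwise the
    nearest preceding explicit date is inherited, and failing that the
    note's authorship date is attached with provenance
    "note-date-default".
    """
    date_part: Optional[ResolvedWhen] = None
    time_part: Optional[ResolvedWhen] = None
    phrasal: Optional[ResolvedWhen] = None
    for span in spans:
        rw = resolve(span, reference, dialect)
        if rw is None:
            continue
        if rw.status == WhenStatus.unresolved_phrasal:
            phrasal = phrasal or rw
        elif rw.time_of_day is not None and time_part is None:
            time_part = rw
        elif rw.date is not None and date_part is None:
            date_part = rw

    if date_part is not None:
        last_date = date_part
        when = ResolvedWhen(
            raw=date_part.raw if time_part is None else f"{date_part.raw} {time_part.raw}",
            date=date_part.date,
            time_of_day=time_part.time_of_day if time_part else None,
            provenance="explicit",
            meridiem_ambiguous=bool(time_part and time_part.meridiem_ambiguous),
        )
        return when, last_date
    if phrasal is not None and time_part is None:
        return phrasal, last_date
    if last_date is not None:
        when = ResolvedWhen(
            raw=(time_part.raw if time_part else last_date.raw),
            date=last_date.date,
            time_of_day=time_part.time_of_day if time_part else None,
            provenance="inherited",
            meridiem_ambiguous=bool(time_part and time_part.meridiem_ambiguous),
        )
        return when, last_date
    when = ResolvedWhen(
        raw=time_part.raw if time_part else "",
        date=reference,
        time_of_day=time_part.time_of_day if time_part else None,
        provenance="note-date-default",
        meridiem_ambiguous=bool(time_part and time_part.meridiem_ambiguous),
    )
    return when, last_date


def extract_note(
    note: Note,
    lexicons: Optional[Dict[Vocabulary, Lexicon]] = None,
    backend: Optional[Backend] = None,
    date_dialect: str = "mdy",
) -> ExtractionResult:
    """Run the full pipeline on one note.

    Deterministic under the rule backend; never raises on note content
    (worst case is an empty result with category "none").
    """
    if lexicons is None:
        lexicons = load_lexicon_dir()
    med_lex = lexicons[Vocabulary.medication]
    sym_lex = lexicons[Vocabulary.symptom]
    unit_lex = lexicons[Vocabulary.unit]
    trigger_lex = lexicons.get(Vocabulary.temporal_trigger)

    if backend is None:
        backend = get_backend(
            "rule",
            unit_terms=unit_lex.single_token_terms(),
            medication_terms=med_lex.single_token_terms(),
            symptom_terms=sym_lex.single_token_terms(),
        )

    sentences = analyze(note.text, backend)
    med_mentions = match_entities(sentences, note.text, med_lex)
    sym_mentions = match_entities(sentences, note.text, sym_lex)

    # cross-vocabulary ambiguity resolves to medication (deterministic tie-break)
    kept_syms = []
    for sm in sym_mentions:
        if any(not (sm.end <= mm.start or sm.start >= mm.end) for mm in med_mentions):
            logger.info(
                "note %s: %r matched both medication and symptom lexicons; kept as medication",
                note.note_id,
                sm.surface,
            )
            continue
        kept_syms.append(sm)

    reference = note.reference_date
    instances: List[MedicationInstance] = []
    last_date: Optional[ResolvedWhen] = None
    for s_idx, sentence in enumerate(sentences):
        sent_meds = [m for m in med_mentions if m.sentence_index == s_idx]
        spans = detect_temporal(sentence, note.text, trigger_lex)
        pairs = find_quantity_unit_pairs(
            sentence, unit_lex, [m.head_token_index for m in sent_meds]
        )
        drafts = attach_to_medication(pairs, sent_meds, sentence, unit_lex)
        when, last_date = _sentence_when(spans, reference, date_dialect, last_date)
        for draft in drafts:
            instances.append(
                draft.model_copy(update={"when": when, "evidence_sentence": s_idx})
            )

    symptoms = extract_symptoms(kept_syms)
    result = ExtractionResult(
        note_id=note.note_id,
        medication_instances=instances,
        symptom_mentions=symptoms,
    )
    result.category = categorize(result)
    return result


def extract_corpus(
    notes: Sequence[Note],
    lexicons: Optional[Dict[Vocabulary, Lexicon]] = None,
    backend: Optional[Backend] = None,
    date_dialect: str = "mdy",
) -> List[ExtractionResult]:
    """Extract every note independently (per-note results are order-free)."""
    if lexicons is None:
        lexicons = load_lexicon_dir()
    return [extract_note(n, lexicons, backend, date_dialect) for n in notes]
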