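"""Sentence splitting, tokenization, POS tagging, and dependency parsing.

The pipeline's extraction rules only consume coarse structure — a 10-tag
POS inventory and a per-sentence dependency tree — so the backend is a
pluggable contract.  Two backends are provided:

``rule`` (alias ``fallback``, the default)
    A deterministic, pure-Python parser.  Tokenization keeps decimal
    numbers ("2.6"), clock times ("6:00"), and numeric ranges ("1-2") as
    single tokens so dose and time atoms survive.  POS tags come from
    numeric patterns, small closed word classes, and lexicon hints (unit
    terms are NOUN, medication terms PROPN).  Dependencies follow three
    rules: a NUM immediately preceding a NOUN/PROPN is its ``nummod``
    child; a preposition attaches (``prep``) to the nearest preceding
    VERB or NOUN; everything else attaches to the sentence root (first
    VERB, else first NOUN/PROPN, else first token).  The output is always
    a valid single-rooted acyclic tree.

``pretrained``
    Wraps an external spaCy-compatible biomedical model suite if one is
    importable; the model name is configuration, never hard-coded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Protocol, Sequence

COARSE_TAGS = ("NOUN", "PROPN", "VERB", "NUM", "ADP", "DET", "ADJ", "ADV", "PUNCT", "OTHER")

CLOCK_RE = re.compile(r"^\d{1,2}:\d{2}$")
NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?(?:-\d+(?:\.\d+)?)?$")

# Token pattern: clock time | number/decimal/range | word | any one non-space char.
_TOKEN_RE = re.compile(
    r"\d{1,2}:\d{2}"
    r"|\d+(?:\.\d+)?(?:-\d+(?:\.\d+)?)?"
    r"|[A-Za-z]+(?:'[A-Za-z]+)?"
    r"|[^\sA-Za-z0-9]"
)

_ADPOSITIONS = frozenset(
    "at of in on to for with by over after before during from into under about".split()
)
_DETERMINERS = frozenset("a an the this that these those his her their its my our your".split())
_VERBS = frozenset(
    """gave give given giving take takes took taking taken started start starts starting
    stopped stop stops is are was were be been being has have had having will would can
    could should continue continues continued switch switched switching seems seemed seem
    feels felt feel got get gets getting went go goes going doing does do did complains
    complained reports reported said says slept sleeps ate eats drank drinks used uses
    administered administers hanging""".split()
)
_ADVERBS = frozenset(
    "today yesterday tonight tomorrow now still overall again then ago very really just".split()
)
_ADJECTIVES = frozenset(
    "runny sore good bad final another few little high low red swollen itchy stuffy".split()
)


@dataclass(frozen=True)
class ParsedToken:
    """One token with offsets into the note text and a dependency arc."""

    index: int
    surface: str
    start: int
    end: int
    pos: str
    head: int  # index of governing token within the sentence; self for root
    dep_label: str


@dataclass(frozen=True)
class ParsedSentence:
    tokens: Sequence[ParsedToken]
    sent_start: int
    sent_end: int


class BackendUnavailableError(RuntimeError):
    """Raised when a requested parsing backend cannot be constructed."""


class Backend(Protocol):
    name: str

    def parse(self, text: str) -> List[ParsedSentence]: ...


def split_sentences(text: str) -> List[tuple[int, int]]:
    """Return [start, end) spans of sentences.

    A boundary is a run of ``. ! ? …`` where a period does not sit between
    two digits (so "2.6" never splits).  Transcribed notes frequently use
    an ellipsis as the only separator, so it terminates a sentence too.
    """
    spans: List[tuple[int, int]] = []
    n = len(text)
    i = 0
    start = 0
    while i < n:
        ch = text[i]
        is_term = ch in "!?…" or (
            ch == "."
            and not (0 < i < n - 1 and text[i - 1].isdigit() and text[i + 1].isdigit())
        )
        if is_term:
            # consume the whole terminator run
            j = i + 1
            while j < n and text[j] in ".!?…":
                j += 1
            spans.append((start, j))
            start = j
            i = j
        else:
            i += 1
    if start < n and text[start:].strip():
        spans.append((start, n))
    # trim leading/trailing whitespace off each span, drop empty ones
    trimmed = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    return trimmed


def tokenize(text: str, offset: int = 0) -> List[tuple[str, int, int]]:
    """Tokenize ``text``; offsets are shifted by ``offset`` into the full note."""
    return [
        (m.group(0), m.start() + offset, m.end() + offset) for m in _TOKEN_RE.finditer(text)
    ]


@dataclass
class RuleBackend:
    """Deterministic rule-based sentence splitter + tagger + parser.

    ``unit_terms`` / ``medication_terms`` / ``symptom_terms`` are sets of
    normalized single tokens used as POS hints; they typically come from
    the loaded lexicons.
    """

    unit_terms: frozenset = frozenset()
    medication_terms: frozenset = frozenset()
    symptom_terms: frozenset = frozenset()
    name: str = field(default="rule", init=False)

    def parse(self, text: str) -> List[ParsedSentence]:
        sentences = []
        for s, e in split_sentences(text):
            toks = tokenize(text[s:e], offset=s)
            if toks:
                sentences.append(self._parse_sentence(toks, s, e))
        return sentences

    def _tag(self, surface: str, index: int) -> str:
        lower = surface.lower()
        if CLOCK_RE.match(surface) or NUMBER_RE.match(surface):
            return "NUM"
        if not any(c.isalnum() for c in surface):
            return "PUNCT"
        if lower in self.unit_terms:
            return "NOUN"
        if lower in self.medication_terms:
            return "PROPN"
        if lower in self.symptom_terms:
            return "NOUN"
        if lower in _ADPOSITIONS:
            return "ADP"
        if lower in _DETERMINERS:
            return "DET"
        if lower in _VERBS:
            return "VERB"
        if lower in _ADVERBS:
            return "ADV"
        if lower in _ADJECTIVES:
            return "ADJ"
        if surface[0].isupper() and index > 0:
            return "PROPN"
        return "NOUN"

    def _parse_sentence(
        self, toks: List[tuple[str, int, int]], sent_start: int, sent_end: int
    ) -> ParsedSentence:
        pos = [self._tag(surface, i) for i, (surface, _, _) in enumerate(toks)]
        n = len(toks)

        root = next((i for i in range(n) if pos[i] == "VERB"), None)
        if root is None:
            root = next((i for i in range(n) if pos[i] in ("NOUN", "PROPN")), 0)

        heads = [root] * n
        labels = ["dep"] * n
        heads[root], labels[root] = root, "root"
        for i in range(n):
            if i == root:
                continue
            if pos[i] == "NUM" and i + 1 < n and pos[i + 1] in ("NOUN", "PROPN"):
                heads[i], labels[i] = i + 1, "nummod"
            elif pos[i] == "ADP":
                gov = next(
                    (j for j in range(i - 1, -1, -1) if pos[j] in ("VERB", "NOUN", "PROPN")),
                    root,
                )
                # never attach to a forward-pointing child of ourselves (cannot
                # happen under these rules, but keep root as the safe fallback)
                heads[i], labels[i] = (gov, "prep") if gov != i else (root, "dep")

        tokens = [
            ParsedToken(
                index=i,
                surface=surface,
                start=start,
                end=end,
                pos=pos[i],
                head=heads[i],
                dep_label=labels[i],
            )
            for i, (surface, start, end) in enumerate(toks)
        ]
        return ParsedSentence(tokens=tokens, sent_start=sent_start, sent_end=sent_end)


class PretrainedBackend:
    """spaCy-model-backed parser; requires the model suite to be installed."""

    name = "pretrained"

    _POS_MAP = {
        "NOUN": "NOUN", "PROPN": "PROPN", "VERB": "VERB", "AUX": "VERB", "NUM": "NUM",
        "ADP": "ADP", "DET": "DET", "ADJ": "ADJ", "ADV": "ADV", "PUNCT": "PUNCT",
    }

    def __init__(self, model: str):
        try:
            import spacy  # type: ignore
        except ImportError as exc:
            raise BackendUnavailableError(
                "backend 'pretrained' requires the spaCy model suite, which is not "
                "installed; use backend 'rule' or install spacy and the model "
                f"{model!r}"
            ) from exc
        try:
            self._nlp = spacy.load(model)
        except OSError as exc:  # pragma: no cover - requires model download
            raise BackendUnavailableError(
                f"backend 'pretrained': model {model!r} is not available locally"
            ) from exc

    def parse(self, text: str) -> List[ParsedSentence]:  # pragma: no cover - optional path
        doc = self._nlp(text)
        sentences = []
        for sent in doc.sents:
            toks = list(sent)
            index_of = {t.i: k for k, t in enumerate(toks)}
            tokens = [
                ParsedToken(
                    index=k,
                    surface=t.text,
                    start=t.idx,
                    end=t.idx + len(t.text),
                    pos=self._POS_MAP.get(t.pos_, "OTHER"),
                    head=index_of.get(t.head.i, k) if t.head.i != t.i else k,
                    dep_label="root" if t.head.i == t.i or t.dep_ == "ROOT" else t.dep_,
                )
                for k, t in enumerate(toks)
            ]
            sentences.append(
                ParsedSentence(tokens=tokens, sent_start=sent.start_char, sent_end=sent.end_char)
            )
        return sentences


def get_backend(
    name: str = "rule",
    *,
    unit_terms: Iterable[str] = (),
    medication_terms: Iterable[str] = (),
    symptom_terms: Iterable[str] = (),
    model: Optional[str] = None,
) -> Backend:
    """Construct a parsing backend by name (``rule``/``fallback`` or ``pretrained``)."""
    if name in ("rule", "fallback"):
        return RuleBackend(
            unit_terms=frozenset(unit_terms),
            medication_terms=frozenset(medication_terms),
            symptom_terms=frozenset(symptom_terms),
        )
    if name == "pretrained":
        if not model:
            raise BackendUnavailableError(
                "backend 'pretrained' needs an explicit model name in configuration"
            )
        return PretrainedBackend(model)
    raise BackendUnavailableError(f"unknown parsing backend {name!r}")


def analyze(text: str, backend: Backend) -> List[ParsedSentence]:
    """Parse ``text`` into sentences; empty/whitespace text yields an empty list."""
    if not text or not text.strip():
        return []
    return backend.parse(text)


def validate_tree(sentence: ParsedSentence, note_text: Optional[str] = None) -> None:
    """Assert the structural invariants of a parsed sentence (test helper).

    Checks span/offset consistency, a unique self-headed root, and that
    following head pointers from every token terminates at the root.
    """
    toks = list(sentence.tokens)
    roots = [t for t in toks if t.head == t.index]
    assert len(roots) == 1, f"expected exactly one root, got {len(roots)}"
    prev_end = None
    for t in toks:
        assert 0 <= t.start < t.end, (t.start, t.end)
        assert sentence.sent_start <= t.start and t.end <= sentence.sent_end
        assert 0 <= t.head < len(toks)
        assert t.pos in COARSE_TAGS
        if note_text is not None:
            assert note_text[t.start : t.end] == t.surface
        if prev_end is not None:
            assert t.start >= prev_end, "tokens overlap or are out of order"
        prev_end = t.end
        # walk to root
        seen = set()
        cur = t.index
        while toks[cur].head != cur:
            assert cur not in seen, "cycle in dependency tree"
            seen.add(cur)
            cur = toks[cur].head
        assert cur == roots[0].index
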