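"""Ontology-subset lexicons and dictionary-based entity recognition.

Medication terms link to RxNorm-style concept ids, symptom terms to
SNOMED-CT-style ids, plus a measurement-unit lexicon and a relative-date
trigger lexicon.  Lexicons are flat 3-column TSVs
(``term<TAB>canonical<TAB>concept_id``; ``#`` comment lines allowed), so
user-supplied full ontology exports in the same shape drop in for the
bundled illustrative subsets.

Mention recognition is greedy longest dictionary match, left to right,
over token n-grams after normalization — exact match only, which keeps
the pipeline zero-shot and reproduces the dictionary error modes of real
ontologies (e.g. "water" matching a medication ingredient).
"""

from __future__ import annotations

import enum
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

from pydantic import BaseModel

from pghdkit.parsing import ParsedSentence

logger = logging.getLogger(__name__)


class Vocabulary(str, enum.Enum):
    medication = "medication"
    symptom = "symptom"
    unit = "unit"
    temporal_trigger = "temporal_trigger"


_EDGE_PUNCT_RE = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    """Normalize a term for dictionary lookup.

    Lowercase, collapse internal whitespace to single spaces, strip
    leading/trailing punctuation.  Idempotent by construction.
    """
    s = unicodedata.normalize("NFKC", raw).lower()
    s = _WS_RE.sub(" ", s).strip()
    return _EDGE_PUNCT_RE.sub("", s)


@dataclass
class Lexicon:
    """Normalized term → (canonical name, concept id) dictionary."""

    vocabulary: Vocabulary
    entries: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    @property
    def max_term_tokens(self) -> int:
        return max((len(t.split()) for t in self.entries), default=0)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.entries

    def lookup(self, term: str) -> Tuple[str, str]:
        return self.entries[normalize_term(term)]

    def single_token_terms(self) -> frozenset:
        """Single-token normalized terms, used as POS hints by the rule parser."""
        return frozenset(t for t in self.entries if " " not in t)


class EntityMention(BaseModel):
    """A text span matched against a lexicon and linked to a concept."""

    start: int
    end: int
    surface: str
    vocabulary: Vocabulary
    concept_id: str
    canonical: str
    sentence_index: int
    head_token_index: int  # last token of the match (head-final convention)


def load_lexicon(path: Union[str, Path], vocabulary: Union[str, Vocabulary]) -> Lexicon:
    """Load a 3-column TSV lexicon.

    Duplicate normalized terms keep the first row (with a warning); an
    empty or column-deficient file is a hard error.
    """
    vocabulary = Vocabulary(vocabulary)
    path = Path(path)
    lex = Lexicon(vocabulary=vocabulary)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns "
                    f"(term, canonical, concept_id), got {len(parts)}"
                )
            term, canonical, concept_id = (p.strip() for p in parts[:3])
            key = normalize_term(term)
            if not key or not concept_id:
                raise ValueError(f"{path}:{lineno}: empty term or concept_id")
            if key in lex.entries:
                logger.warning(
                    "%s:%d: duplicate term %r, keeping first occurrence", path, lineno, key
                )
                continue
            lex.entries[key] = (canonical, concept_id)
    if not lex.entries:
        raise ValueError(f"lexicon file {path} contains no entries")
    return lex


def default_lexicon_dir() -> Path:
    """Directory of the bundled illustrative lexicon subsets."""
    return Path(str(resources.files("pghdkit") / "data" / "lexicons"))


_LEXICON_FILES = {
    Vocabulary.medication: "medications.tsv",
    Vocabulary.symptom: "symptoms.tsv",
    Vocabulary.unit: "units.tsv",
    Vocabulary.temporal_trigger: "temporal_triggers.tsv",
}


def load_lexicon_dir(directory: Union[str, Path, None] = None) -> Dict[Vocabulary, Lexicon]:
    """Load the four standard lexicons from a directory (bundled by default)."""
    directory = Path(directory) if directory is not None else default_lexicon_dir()
    return {
        vocab: load_lexicon(directory / fname, vocab)
        for vocab, fname in _LEXICON_FILES.items()
    }


def match_entities(
    sentences: Sequence[ParsedSentence], text: str, lexicon: Lexicon
) -> List[EntityMention]:
    """Greedy longest-match dictionary NER over token n-grams.

    Within each sentence, non-punctuation tokens are scanned left to
    right; at each position the longest n-gram (up to the lexicon's
    longest entry) that matches a normalized term is emitted and its
    tokens are consumed, so mentions never overlap and a term that is a
    prefix of a longer matching term is suppressed in its favour.
    """
    mentions: List[EntityMention] = []
    max_n = lexicon.max_term_tokens
    if max_n == 0:
        return mentions
    for s_idx, sent in enumerate(sentences):
        word_toks = [t for t in sent.tokens if t.pos != "PUNCT"]
        i = 0
        while i < len(word_toks):
            matched = False
            for n in range(min(max_n, len(word_toks) - i), 0, -1):
                gram = word_toks[i : i + n]
                key = normalize_term(" ".join(t.surface for t in gram))
                if key in lexicon.entries:
                    canonical, concept_id = lexicon.entries[key]
                    start, end = gram[0].start, gram[-1].end
                    mentions.append(
                        EntityMention(
                            start=start,
                            end=end,
                            surface=text[start:end],
                            vocabulary=lexicon.vocabulary,
                            concept_id=concept_id,
                            canonical=canonical,
                            sentence_index=s_idx,
                            head_token_index=gram[-1].index,
                        )
                    )
                    i += n
                    matched = True
                    break
            if not matched:
                i += 1
    return mentions
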