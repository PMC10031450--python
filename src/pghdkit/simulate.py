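"""Synthetic caregiver-note corpora with known gold annotations.

The study corpus this generator emulates is private: 87 short (1-3
sentence) voice-transcribed or typed notes by caregivers of children
with special health care needs, mixing medication events (name + dose +
unit + time), symptom observations, and small talk.  Defaults mirror the
study conditions: the category mix medication-only / symptom-only /
both / neither at 17/33/13/24 out of 87, and 18% of notes carrying at
least one transcription-style error.

Gold annotations are emitted at generation time from the template
parameters — never re-derived from the text — so transcription noise
creates genuine prediction-vs-gold divergence, exactly like human gold
against a noisy transcript.  All randomness flows through one seeded
``random.Random`` passed explicitly.
"""

from __future__ import annotations

import random
import re
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

from pghdkit.corpus import Modality, Note, NoteCategory
from pghdkit.lexicon import Lexicon, Vocabulary, load_lexicon_dir
from pghdkit.metrics import GoldAnnotation, GoldInstance, GoldWhen

# Template pools: every term is a canonical entry of the bundled lexicons,
# so a noise-free corpus is perfectly extractable by dictionary matching.
_MED_POOL = [
    "benadryl", "tylenol", "zyrtec", "claritin", "singulair", "albuterol",
    "keppra", "gabapentin", "baclofen", "melatonin", "miralax", "prednisone",
    "amoxicillin", "ibuprofen", "clonidine", "lamictal", "trileptal", "zofran",
    "omeprazole", "neurontin", "ferrous sulfate", "folic acid",
]
_SYMPTOM_POOL = [
    "fever", "runny nose", "cough", "congestion", "sore throat", "headache",
    "nausea", "vomiting", "diarrhea", "constipation", "rash", "hives",
    "seizures", "tremor", "wheezing", "fatigue", "drowsiness", "insomnia",
    "dizziness", "drooling", "reflux", "irritability", "anxiety", "happiness",
    "sadness", "agitation", "restlessness", "sneezing", "chills", "weakness",
    "stomach ache", "earache",
]
_NAMES = ["Alex", "Jamie", "Sam", "Taylor", "Jordan", "Casey", "Morgan", "Riley"]
# "Yasmin" is both a plausible first name and a brand-name lexicon entry;
# enabling it reproduces the name/medication false-positive error mode.
_CONFOUND_NAMES = ["Yasmin"]
_FILLERS = [
    "Overall doing okay.",
    "Quiet day at home.",
    "Slept through the night.",
    "Went to school as usual.",
    "Played outside for a bit.",
    "Nothing new to report.",
]
_LIQUID_UNITS = ["ml", "mg", "tsp"]

# Homophone / near-phonetic confusion table for transcription-style noise.
ASR_CONFUSIONS: Dict[str, str] = {
    "benadryl": "bena drill",
    "tylenol": "tile in all",
    "gabapentin": "gaba pentin",
    "zyrtec": "zer tech",
    "keppra": "kep ruh",
    "albuterol": "al beuter all",
    "melatonin": "mela tone in",
    "miralax": "mira lacks",
    "claritin": "clara ten",
    "singulair": "sing you lair",
    "baclofen": "back low fen",
    "prednisone": "pred in zone",
    "amoxicillin": "a mock sa cillin",
    "ibuprofen": "i be profen",
    "clonidine": "klon a deen",
    "ml": "mil",
    "mg": "em gee",
}
_NUMBER_WORDS = {
    "1": "one", "2": "two", "3": "three", "4": "four", "5": "five",
    "6": "six", "7": "seven", "8": "eight", "9": "nine", "10": "ten",
}

DEFAULT_CATEGORY_MIX = {
    NoteCategory.medication_only: 17 / 87,
    NoteCategory.symptom_only: 33 / 87,
    NoteCategory.both: 13 / 87,
    NoteCategory.none: 24 / 87,
}


class GeneratorConfig(BaseModel):
    n_notes: int = Field(87, ge=1)
    category_mix: Dict[NoteCategory, float] = Field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    asr_error_note_rate: float = Field(0.18, ge=0.0, le=1.0)
    seed: int = 0
    start_date: date = date(2020, 11, 2)
    voice_fraction: float = Field(78 / 87, ge=0.0, le=1.0)
    confound_names: bool = False
    lexicon_dir: Optional[Path] = None

    @model_validator(mode="after")
    def _mix_sums_to_one(self) -> "GeneratorConfig":
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1, got {total}")
        return self


def apply_asr_noise(text: str, intensity: float, rng: random.Random) -> str:
    """Transcription-noise channel.

    With probability ``intensity`` the note receives 1-3 corruptions:
    near-phonetic substitution of a medication/unit word (preferred when
    one is present), a digit spelled out as a word, casing loss, or a
    dropped sentence terminator.  ``intensity`` 0 returns the text
    unchanged.
    """
    if intensity <= 0 or rng.random() >= intensity:
        return text
    n_edits = rng.randint(1, 3)
    for edit_i in range(n_edits):
        phonetic = [
            (key, sub)
            for key, sub in ASR_CONFUSIONS.items()
            if re.search(r"\b" + re.escape(key) + r"\b", text, re.IGNORECASE)
        ]
        ops = []
        if phonetic:
            ops.append("phonetic")
        if re.search(r"\b(10|[1-9])\b", text):
            ops.append("number_word")
        ops.extend(["casing", "punct_drop"])
        # the first edit targets the lexicon when possible: that is what
        # actually breaks dictionary matching, as in real transcripts
        op = "phonetic" if (edit_i == 0 and phonetic) else rng.choice(ops)
        if op == "phonetic" and phonetic:
            key, sub = phonetic[rng.randrange(len(phonetic))]
            text = re.sub(r"\b" + re.escape(key) + r"\b", sub, text, count=1, flags=re.IGNORECASE)
        elif op == "number_word":
            m = re.search(r"\b(10|[1-9])\b", text)
            if m:
                text = text[: m.start()] + _NUMBER_WORDS[m.group(1)] + text[m.end() :]
        elif op == "casing":
            text = text.lower()
        else:  # punct_drop
            dots = [i for i, c in enumerate(text) if c in ".!?"]
            if dots:
                i = dots[rng.randrange(len(dots))]
                text = text[:i] + text[i + 1 :]
    return text


def _fmt_qty(q: float) -> str:
    return f"{q:g}"


class _NoteBuilder:
    def __init__(self, rng: random.Random, lexicons: Dict[Vocabulary, Lexicon], names: List[str]):
        self.rng = rng
        self.med_lex = lexicons[Vocabulary.medication]
        self.sym_lex = lexicons[Vocabulary.symptom]
        self.names = names

    def _med_surface(self, term: str) -> Tuple[str, str]:
        canonical, _ = self.med_lex.lookup(term)
        surface = " ".join(w.capitalize() for w in term.split())
        return surface, canonical

    def med_sentence(self, ref: date) -> Tuple[str, List[GoldInstance]]:
        rng = self.rng
        template = rng.choice(["dose_time", "rate", "yesterday_dose", "taper", "bare"])
        if template == "dose_time":
            # count-like doses ("2 Benadryl") read naturally only with
            # single-word names
            term = rng.choice([t for t in _MED_POOL if " " not in t])
        else:
            term = rng.choice(_MED_POOL)
        surface, canonical = self._med_surface(term)
        if template == "dose_time":
            q = rng.randint(1, 3)
            hh = rng.randint(1, 12)
            mm = rng.choice([0, 15, 30, 45])
            mer = rng.choice(["am", "pm"])
            h24 = hh % 12 + (12 if mer == "pm" else 0)
            text = f"Gave {rng.choice(self.names)} {q} {surface} at {hh}:{mm:02d} {mer}."
            gold = [GoldInstance(medication=canonical, quantity=float(q),
                                 when=GoldWhen(time_of_day=time(h24, mm)))]
        elif template == "rate":
            q = round(rng.uniform(0.5, 8.0), 1)
            unit = rng.choice(_LIQUID_UNITS)
            text = f"Started {surface} at a rate of {_fmt_qty(q)} {unit}."
            gold = [GoldInstance(medication=canonical, quantity=q, unit=unit)]
        elif template == "yesterday_dose":
            q = rng.randint(1, 10)
            unit = rng.choice(_LIQUID_UNITS)
            text = f"Yesterday we gave {q} {unit} of {surface}."
            gold = [GoldInstance(medication=canonical, quantity=float(q), unit=unit,
                                 when=GoldWhen(date=ref - timedelta(days=1)))]
        elif template == "taper":
            k = rng.randint(2, 4)
            q0 = rng.choice([2.6, 3.2, 4.0, 5.0])
            rates = [round(q0 - 0.6 * i, 1) for i in range(k)]
            parts = [f"We started {surface} at a rate of {_fmt_qty(rates[0])} ml"]
            for r in rates[1:-1]:
                parts.append(f", then switched to {_fmt_qty(r)} ml")
            parts.append(f" with final rate at {_fmt_qty(rates[-1])} ml.")
            text = "".join(parts)
            gold = [GoldInstance(medication=canonical, quantity=r, unit="ml") for r in rates]
        else:  # bare
            text = f"{rng.choice(self.names)} does not want to take {surface} again."
            gold = [GoldInstance(medication=canonical)]
        return text, gold

    def symptom_sentence(self) -> Tuple[str, List[str]]:
        rng = self.rng
        template = rng.choice(["has_but_no", "complained", "dealing"])
        s1 = rng.choice(_SYMPTOM_POOL)
        s2 = rng.choice(_SYMPTOM_POOL)
        c1, _ = self.sym_lex.lookup(s1)
        c2, _ = self.sym_lex.lookup(s2)
        if template == "has_but_no":
            return f"Has a {s1} but no {s2}.", [c1, c2]
        if template == "complained":
            return f"{rng.choice(self.names)} complained of {s1} today.", [c1]
        return f"Still dealing with {s1} and some {s2}.", [c1, c2]


def generate_corpus(config: GeneratorConfig) -> Tuple[List[Note], List[GoldAnnotation]]:
    """Build (notes, gold) deterministically from the config seed."""
    rng = random.Random(config.seed)
    lexicons = load_lexicon_dir(config.lexicon_dir)
    names = _NAMES + (_CONFOUND_NAMES if config.confound_names else [])
    builder = _NoteBuilder(rng, lexicons, names)

    categories = list(config.category_mix.keys())
    weights = [config.category_mix[c] for c in categories]

    notes: List[Note] = []
    golds: List[GoldAnnotation] = []
    for i in range(config.n_notes):
        note_id = f"note-{i:04d}"
        authored = datetime.combine(
            config.start_date + timedelta(days=rng.randrange(14)),
            time(rng.randint(7, 21), rng.randint(0, 59)),
        )
        ref = authored.date()
        category = rng.choices(categories, weights=weights, k=1)[0]

        sentences: List[str] = []
        gold_instances: List[GoldInstance] = []
        gold_symptoms: List[str] = []
        if category in (NoteCategory.medication_only, NoteCategory.both):
            for _ in range(1 if category == NoteCategory.both else rng.choice([1, 1, 2])):
                text, gold = builder.med_sentence(ref)
                sentences.append(text)
                gold_instances.extend(gold)
        if category in (NoteCategory.symptom_only, NoteCategory.both):
            for _ in range(1 if category == NoteCategory.both else rng.choice([1, 1, 2])):
                text, canonicals = builder.symptom_sentence()
                sentences.append(text)
                gold_symptoms.extend(canonicals)
        if category == NoteCategory.none:
            for _ in range(rng.choice([1, 2])):
                sentences.append(rng.choice(_FILLERS))
        if len(sentences) < 3 and rng.random() < 0.3:
            sentences.append(rng.choice(_FILLERS))

        text = " ".join(sentences)
        text = apply_asr_noise(text, config.asr_error_note_rate, rng)
        modality = (
            Modality.voice_transcript if rng.random() < config.voice_fraction else Modality.typed
        )
        notes.append(
            Note(
                note_id=note_id,
                text=text,
                authored_at=authored,
                modality=modality,
                author_id=f"parent-{rng.randint(1, 24):02d}",
            )
        )
        golds.append(
            GoldAnnotation(note_id=note_id, instances=gold_instances, symptoms=gold_symptoms)
        )
    return notes, golds
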