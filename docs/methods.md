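# Methods

## Problem and pipeline

`pghdkit` extracts two record types from short free-text caregiver/patient
notes: medication instances (name + optional quantity, unit, date/time)
and symptom mentions. The approach is zero-shot: no task-specific
training, only pretrained-or-rule parsing, ontology-subset dictionaries,
and syntactic rules. Per note the stages are: sentence split and
dependency parse → dictionary NER over three lexicons → quantity/unit
pairing by dependency rules → attachment of pairs and of normalized
temporal expressions to medication mentions → categorization of the note
as medication-only / symptom-only / both / none.

## Parsing backends

The extraction rules consume only coarse structure — a 10-tag POS set
(NOUN, PROPN, VERB, NUM, ADP, DET, ADJ, ADV, PUNCT, OTHER) and one
dependency tree per sentence — so the parser is pluggable. The default
`rule` backend is deterministic and pure Python:

- **Tokenizer.** Whitespace/punctuation splitting that preserves dose
  and time atoms: decimals ("2.6"), clock times ("6:00"), and numeric
  ranges ("1-2") stay single tokens.
- **Sentence boundaries** are runs of `. ! ? …` except a period between
  two digits. Ellipses terminate sentences because voice transcripts
  often use them as the only separator.
- **POS** from numeric patterns, small closed word classes
  (prepositions, determiners, a common-verb list), lexicon hints (unit
  terms → NOUN, medication terms → PROPN), capitalization (mid-sentence
  capitalized → PROPN), default NOUN.
- **Dependencies**: root is the first verb (else first noun, else first
  token); a NUM immediately before a NOUN/PROPN is its `nummod` child;
  a preposition attaches to the nearest preceding verb/noun; everything
  else attaches to the root. The construction cannot produce cycles, so
  every sentence is a valid single-rooted tree, fuzz-tested on
  arbitrary text.

A `pretrained` backend wraps an external spaCy-compatible biomedical
model if available (model name is configuration); its tags are mapped
into the same coarse inventory. All shipped tests and results use the
rule backend.

## Lexicons and NER

Lexicons are flat TSVs (`term<TAB>canonical<TAB>concept_id`): ~125
medication rows (brand + generic pairs, RxNorm-style ids), ~80 symptom
rows (SNOMED-CT-style ids, including mood terms such as "happiness",
which are kept in scope as symptoms), ~27 unit rows, and a relative-date
trigger table. The bundled files are small illustrative subsets —
full ontologies cannot be redistributed — but the format is the
contract: a user-supplied RxNorm/SNOMED export in the same three-column
shape drops in unchanged.

Matching is exact (after lowercasing, whitespace collapsing, and edge
punctuation stripping), greedy longest-first over token n-grams, left to
right, consuming matched tokens: "water irrigation solution" wins over
its "water" prefix at the same position. There is no fuzzy matching, no
synonym expansion, and no name filtering; a child named after a drug
brand *will* produce a medication false positive (the generator can
reproduce this with `confound_names=True`). A term present in both the
medication and symptom lexicons resolves to medication, logged.

## Quantity, unit, and attachment rules

Within one sentence:

- **Q1**: a NUM whose `nummod` head is a unit-lexicon token →
  (quantity, unit).
- **Q2**: a NUM governed by, or immediately preceding, a medication
  mention's head token → (quantity, no unit).

Each NUM is used at most once (Q1 precedence); tokens matching `hh:mm`
are reserved for temporal extraction and never become quantities, which
is what keeps "2 Benadryl at 6:00 am" from reading 6:00 as a dose.
Ranges take their first number ("1-2" → 1). Each pair attaches to the
medication with the shortest undirected dependency-path distance to the
NUM (ties: character distance, then leftmost). One instance is emitted
per attached pair — a taper enumerated in one sentence becomes one
instance per rate, in text order — and a medication with no pair yields
one bare instance. Rules never cross sentence boundaries; doses split
across sentences are deliberately missed, a faithful error mode of this
pipeline family.

Negation is not modelled: every symptom mention has polarity
`asserted`, so "no fever" contributes a fever mention. This is a known,
documented limitation of the zero-shot design.

## Temporal normalization

Detection covers clock times (`6:00`, `6:00 am`, `6:00 p.m.`), absolute
dates (month-name forms; numeric forms under a `mdy`/`dmy` dialect
switch, default `mdy`), anchored relatives ("yesterday", "today", "last
week", "N days/weeks ago"), and phrasal referents ("a few days ago",
"the other day"). Overlaps resolve longest-first. Resolution is a pure
function of (span, authorship date): "yesterday" → reference − 1 day,
"N days ago" → reference − N, clock times normalized to 24 h with a
`meridiem_ambiguous` flag when am/pm is absent. Phrasal referents stay
`unresolved_phrasal` — no offset is invented.

Attachment: a sentence's resolved expressions apply to all of its
medication instances. A sentence with no date inherits the nearest
preceding resolved date in the note (diary semantics: "Yesterday we
started… <new sentence> gabapentin at 2.6 ml"), else the note's
authorship date is attached with provenance `note-date-default`. The
provenance field makes the imputation distinguishable from extraction.

## Evaluation

Gold annotations are name-anchored (canonical medication name plus
subcomponent values), not span-anchored, mirroring a human-review
protocol that judges output against the sentence. Matching pairs
predicted with gold instances per note by canonical name, in order
within a name. Subcomponent scoring inside a pair: equal → tp; present
in gold but missing → fn; present with a different value → fp + fn;
present only in prediction → fp. Unmatched instances contribute
fp/fn for each presented subcomponent. The `medication_instance`
component applies the all-subcomponents rule: correct iff everything
gold presents is right and nothing spurious is added. Symptoms are
per-note multisets of canonicals. P, R, F1 are micro-averages of
aggregated counts; 0/0 → 0 by logged convention; reports round to 2
decimals.

One scoring choice deserves emphasis: a predicted date with provenance
`note-date-default` is treated as *no extracted date*. Without the
exemption, every gold instance lacking an explicit date would score a
spurious-date false positive purely from the attachment default, which
would measure the attachment policy rather than extraction quality.
Inherited dates (real information from an earlier sentence) are scored
normally.

## Synthetic corpus generator

The generator emulates the study conditions of a private caregiver-note
corpus: 1–3 sentence notes; a category mix of medication-only /
symptom-only / both / none drawn at 17/87, 33/87, 13/87, 24/87; ~90%
voice-transcribed; authorship dates over a two-week window; 18% of
notes receiving at least one transcription-style corruption. Five
medication templates (count dose with clock time, liquid rate,
yesterday-anchored dose, 2–4 step descending rate taper, bare mention)
and three symptom templates (including a negated second symptom, which
gold still lists because the pipeline asserts it) draw exclusively from
canonical lexicon terms, so a noise-free corpus is perfectly
extractable — the basis of the end-to-end oracle test (P = R = F1 = 1.0
for medication and symptom components on 200 notes).

Gold is emitted from the template parameters at generation time and
never re-derived from text, so the noise channel creates genuine
prediction-vs-gold divergence. The channel applies 1–3 edits per
affected note: near-phonetic substitutions from a fixed confusion table
("benadryl" → "bena drill", "ml" → "mil"; no substitution re-enters any
lexicon), digit-to-word swaps, casing loss, and punctuation drops. The
first edit targets a confusable lexicon word when one is present, since
that is what actually breaks dictionary matching in real transcripts.
Mean medication recall over 10 seeds falls monotonically with the noise
rate (≈1.0 / 0.78 / 0.52 at rates 0 / 0.4 / 0.8).

What the generator does **not** emulate: free word order and disfluency
of real speech, measurement observations ("oxygen was around 80"),
cross-sentence dose references, out-of-lexicon drugs and symptoms, and
realistic name diversity. Perfect scores on noise-free synthetic data
therefore demonstrate internal consistency of rules + lexicons, not
expected real-world performance, which is bounded by lexicon coverage
and parse quality.

All randomness flows through a single `random.Random(seed)`; identical
configs give byte-identical corpora, and extraction is deterministic,
so runs are exactly reproducible.

## Numerical and degenerate-input choices

- Offsets are 0-based half-open over code points; every mention slices
  its note text to its surface.
- Quantity equality in scoring uses `isclose` at 1e-9; quantities must
  be strictly positive, and a unit never appears without a quantity
  (enforced by the data model).
- Empty or whitespace-only text is rejected at the `Note` boundary;
  malformed JSONL lines are skipped with warnings, and a file with zero
  valid notes is a hard error.
- Reports use problem sizes chosen for fast, deterministic runs (200
  notes for the oracle, 10 seeds × 50 notes for the noise sweep); the
  properties they check are size-stable.

## Known limitations

- No negation, uncertainty, or temporal intervals ("for one week" is
  not a duration); no frequency/route extraction (b.i.d., PO).
- Exact dictionary matching only; misspellings and unlisted drugs are
  missed by design in v1.
- The rule parser's closed verb/preposition lists are English-specific
  and tuned to diary register.
- Multi-note days are treated as independent notes; no cross-note
  timeline assembly.
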