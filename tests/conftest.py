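from importlib import resources

import pytest

from pghdkit.corpus import read_notes
from pghdkit.lexicon import Vocabulary, load_lexicon_dir
from pghdkit.parsing import get_backend


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicon_dir()


@pytest.fixture(scope="session")
def backend(lexicons):
    return get_backend(
        "rule",
        unit_terms=lexicons[Vocabulary.unit].single_token_terms(),
        medication_terms=lexicons[Vocabulary.medication].single_token_terms(),
        symptom_terms=lexicons[Vocabulary.symptom].single_token_terms(),
    )


@pytest.fixture(scope="session")
def sample_notes():
    path = resources.files("pghdkit") / "data" / "sample_notes.jsonl"
    return read_notes(str(path))


@pytest.fixture(scope="session")
def sample_by_id(sample_notes):
    return {n.note_id: n for n in sample_notes}
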