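import pytest

from asthmanlp.corpus_io import ClinicalNote
from asthmanlp.lexicon import load_lexicons
from asthmanlp.preprocess import default_config, preprocess_note


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicons()


@pytest.fixture(scope="session")
def prep_config():
    return default_config()


@pytest.fixture(scope="session")
def make_sentences(prep_config):
    """Preprocess raw text into Sentence objects (one synthetic note)."""

    def _make(text: str, note_id: str = "n0"):
        note = ClinicalNote(note_id=note_id, patient_id="p0", text=text)
        return preprocess_note(note, prep_config)

    return _make


@pytest.fixture(scope="session")
def make_sentence(make_sentences):
    """Preprocess raw text expected to contain exactly one sentence."""

    def _make(text: str):
        sentences = make_sentences(text)
        assert len(sentences) == 1, f"expected one sentence from {text!r}"
        return sentences[0]

    return _make
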