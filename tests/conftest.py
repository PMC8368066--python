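import numpy as np
import pytest

from seminfer.corpus import Corpus, Session, Token, Utterance
from seminfer import synth


def utt(*spec: tuple[str, str, int, str]) -> Utterance:
    """Build an utterance from (lemma, upos, head, deprel) tuples."""
    return Utterance(tuple(Token(*s) for s in spec))


@pytest.fixture
def you_open_it() -> Utterance:
    return utt(
        ("you", "PRON", 2, "nsubj"),
        ("open", "VERB", 0, "root"),
        ("it", "PRON", 2, "dobj"),
    )


@pytest.fixture
def you_open_the_box() -> Utterance:
    return utt(
        ("you", "PRON", 2, "nsubj"),
        ("open", "VERB", 0, "root"),
        ("the", "DET", 4, "det"),
        ("box", "NOUN", 2, "dobj"),
    )


@pytest.fixture
def run_utt() -> Utterance:
    return utt(("run", "VERB", 0, "root"))


@pytest.fixture
def tiny_corpus(you_open_it, you_open_the_box, run_utt) -> Corpus:
    return Corpus(
        genre="cds",
        sessions=[
            Session(id="s1", utterances=[you_open_it, run_utt]),
            Session(id="s2", utterances=[you_open_the_box]),
        ],
    )


@pytest.fixture(scope="session")
def cds_corpus() -> Corpus:
    corpus, _ = synth.generate_corpus(synth.preset("cds_like"), 10, 100, seed=11)
    return corpus


@pytest.fixture(scope="session")
def ads_corpus() -> Corpus:
    corpus, _ = synth.generate_corpus(synth.preset("ads_like"), 10, 100, seed=12)
    return corpus


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
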