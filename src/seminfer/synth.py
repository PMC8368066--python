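"""Synthetic genre-parameterized corpora.

The generator emulates the statistical contrasts the pipeline is sensitive
to, without any linguistic pretension beyond them:

* child-directed-speech-like (``cds_like``): short, repetitive utterances, a
  high density of nominals (pronouns, nouns) immediately around verbs, a
  large share of one-word utterances, and causative verbs concentrated in a
  few recurrent transitive agent-verb-patient frames ("you open it", "shall
  I open the lid").
* adult-like (``ads_like``): long, lexically and constructionally varied
  utterances with auxiliaries, adverbs and prepositional material around
  verbs, and causatives spread over many frames.
* ``null_contrast``: a cds_like world in which causatives and non-causatives
  draw from the identical frame distribution — the pipeline should find no
  discrimination signal on it.

Utterances are built from frame templates that carry their own dependency
structure (the verb heads its nominal dependents, determiners attach to
their nouns, and so on), so every generated corpus is valid by construction
and the syntax/lexicon layers can be exercised without a parser.  Slot
fillers come from per-class Zipfian lexicons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import Corpus, Session, Token, Utterance
from .discrimination import CAUSATIVES, NONCAUSATIVES

# A frame is a list of slots (cls, head, deprel): `head` is the 0-based frame
# index of the slot's dependency head, or None for the root.  cls "V" is the
# main verb slot; "V2" a secondary (filler) verb; all other classes name
# their UPOS directly.
Slot = tuple[str, int | None, str]
Frame = tuple[Slot, ...]


def _f(*slots: Slot) -> Frame:
    heads = [h for _, h, _ in slots]
    if sum(h is None for h in heads) != 1:
        raise ValueError("frame must have exactly one root slot")
    return tuple(slots)


# --- frame inventories -----------------------------------------------------

CDS_TRANSITIVE: list[tuple[Frame, float]] = [
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("PRON", 1, "dobj")), 3.0),
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("DET", 3, "det"),
        ("NOUN", 1, "dobj")), 3.0),
    (_f(("AUX", 2, "aux"), ("PRON", 2, "nsubj"), ("V", None, "root"),
        ("DET", 4, "det"), ("NOUN", 2, "dobj")), 3.0),
    (_f(("AUX", 2, "aux"), ("PRON", 2, "nsubj"), ("V", None, "root"),
        ("DET", 4, "det"), ("ADJ", 5, "amod"), ("NOUN", 2, "dobj")), 1.5),
    (_f(("V", None, "root"), ("DET", 2, "det"), ("NOUN", 0, "dobj")), 1.5),
    (_f(("V", None, "root"), ("PRON", 0, "dobj")), 0.5),
]

CDS_NONCAUSATIVE: list[tuple[Frame, float]] = [
    (_f(("PRON", 1, "nsubj"), ("V", None, "root")), 1.0),
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("ADV", 1, "advmod")), 2.0),
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("ADP", 1, "prep"),
        ("NOUN", 2, "pobj")), 3.0),
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("ADP", 1, "prep"),
        ("DET", 4, "det"), ("NOUN", 2, "pobj")), 2.0),
    (_f(("V", None, "root"), ("ADV", 0, "advmod")), 0.5),
]

CDS_GENERAL: list[tuple[Frame, float]] = [
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("PRON", 1, "dobj")), 2.0),
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("ADV", 1, "advmod")), 2.0),
    (_f(("AUX", 2, "aux"), ("PRON", 2, "nsubj"), ("V", None, "root"),
        ("DET", 4, "det"), ("ADJ", 5, "amod"), ("NOUN", 2, "dobj")), 2.5),
    (_f(("V", None, "root"),), 0.5),
]

CDS_VERBLESS: list[tuple[Frame, float]] = [
    (_f(("INTJ", None, "root"),), 3.0),
    (_f(("NOUN", None, "root"),), 2.0),
    (_f(("DET", 1, "det"), ("NOUN", None, "root")), 1.0),
]

ADS_TRANSITIVE: list[tuple[Frame, float]] = [
    (_f(("PRON", 2, "nsubj"), ("AUX", 2, "aux"), ("V", None, "root"),
        ("DET", 5, "det"), ("ADJ", 5, "amod"), ("NOUN", 2, "dobj"),
        ("ADP", 2, "prep"), ("DET", 8, "det"), ("NOUN", 6, "pobj")), 2.0),
    (_f(("DET", 1, "det"), ("NOUN", 3, "nsubj"), ("ADV", 3, "advmod"),
        ("V", None, "root"), ("DET", 5, "det"), ("NOUN", 3, "dobj"),
        ("SCONJ", 8, "mark"), ("PRON", 8, "nsubj"), ("V2", 3, "advcl"),
        ("ADV", 8, "advmod")), 2.0),
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("DET", 3, "det"),
        ("NOUN", 1, "dobj"), ("ADP", 1, "prep"), ("DET", 6, "det"),
        ("ADJ", 7, "amod"), ("NOUN", 4, "pobj"), ("CCONJ", 10, "cc"),
        ("ADV", 1, "advmod"), ("ADV", 9, "advmod")), 1.5),
    (_f(("NOUN", 2, "nsubj"), ("AUX", 2, "aux"), ("V", None, "root"),
        ("PRON", 2, "dobj"), ("ADP", 2, "prep"), ("DET", 6, "det"),
        ("NOUN", 4, "pobj"), ("ADV", 2, "advmod")), 1.5),
    (_f(("NOUN", 1, "nsubj"), ("V", None, "root"), ("NOUN", 1, "dobj"),
        ("ADP", 1, "prep"), ("DET", 5, "det"), ("NOUN", 3, "pobj"),
        ("ADV", 1, "advmod")), 1.5),
]

ADS_NONCAUSATIVE: list[tuple[Frame, float]] = [
    (_f(("PRON", 1, "nsubj"), ("V", None, "root"), ("SCONJ", 4, "mark"),
        ("PRON", 4, "nsubj"), ("V2", 1, "ccomp"), ("DET", 6, "det"),
        ("NOUN", 4, "dobj"), ("ADV", 4, "advmod")), 2.0),
    (_f(("DET", 1, "det"), ("NOUN", 3, "nsubj"), ("AUX", 3, "aux"),
        ("V", None, "root"), ("ADV", 3, "advmod"), ("ADP", 3, "prep"),
        ("DET", 7, "det"), ("ADJ", 8, "amod"), ("NOUN", 5, "pobj")), 2.0),
    (_f(("PRON", 2, "nsubj"), ("ADV", 2, "advmod"), ("V", None, "root"),
        ("ADP", 2, "prep"), ("DET", 5, "det"), ("NOUN", 3, "pobj"),
        ("CCONJ", 7, "cc"), ("ADV", 2, "advmod")), 1.5),
    (_f(("NOUN", 1, "nsubj"), ("V", None, "root"), ("ADP", 1, "prep"),
        ("NOUN", 2, "pobj"), ("ADV", 1, "advmod"), ("SCONJ", 7, "mark"),
        ("PRON", 7, "nsubj"), ("V2", 1, "advcl")), 1.5),
]

ADS_GENERAL: list[tuple[Frame, float]] = ADS_TRANSITIVE[:2] + ADS_NONCAUSATIVE[:2] + [
    (_f(("ADV", 1, "advmod"), ("V", None, "root"), ("PRON", 1, "nsubj"),
        ("AUX", 1, "aux"), ("DET", 5, "det"), ("NOUN", 1, "dobj"),
        ("ADP", 1, "prep"), ("NOUN", 6, "pobj"), ("ADV", 1, "advmod"),
        ("SCONJ", 11, "mark"), ("PRON", 11, "nsubj"), ("V2", 1, "advcl")), 1.0),
]

ADS_VERBLESS: list[tuple[Frame, float]] = [
    (_f(("INTJ", None, "root"),), 1.0),
    (_f(("DET", 2, "det"), ("ADJ", 2, "amod"), ("NOUN", None, "root")), 1.0),
]


def _default_lexicon(n_nouns: int, n_adjs: int, n_advs: int,
                     n_filler_verbs: int) -> dict[str, list[str]]:
    return {
        "PRON": ["you", "i", "it", "he", "she", "we", "they", "this"],
        "DET": ["the", "a", "that", "some"],
        "NOUN": [f"noun{i:03d}" for i in range(n_nouns)],
        "ADJ": [f"adj{i:02d}" for i in range(n_adjs)],
        "ADV": [f"adv{i:02d}" for i in range(n_advs)],
        "ADP": ["in", "on", "with", "at", "of", "to"],
        "AUX": ["do", "can", "will", "shall", "be"],
        "INTJ": ["oh", "yes", "no", "wow", "hm"],
        "SCONJ": ["because", "if", "when"],
        "CCONJ": ["and", "but", "or"],
        "V2": [f"vrb{i:02d}" for i in range(n_filler_verbs)],
    }


@dataclass
class GenreSpec:
    """Generating parameters for one genre; the stated world of the tests."""

    genre: str
    mean_utterance_length: float
    one_word_utterance_rate: float  # via the verbless length-1 frames
    verbless_rate: float
    frame_concentration: float  # weights ~ base**(1/c): low c = repetitive
    nominal_density: float  # descriptive target, see docs
    causative_frame_bias: float
    noncausative_frame_bias: float
    target_verb_rate: float = 0.5  # share of verb slots filled by target verbs
    pp_recursion_rate: float = 0.0  # chance of appending each extra PP to the verb
    zipf_exponent: float = 1.0
    transitive_frames: list = field(default_factory=list)
    noncausative_frames: list = field(default_factory=list)
    general_frames: list = field(default_factory=list)
    verbless_frames: list = field(default_factory=list)
    lexicon: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.verbless_rate, self.causative_frame_bias,
                  self.noncausative_frame_bias, self.target_verb_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.frame_concentration <= 0:
            raise ValueError("frame_concentration must be positive")


@dataclass
class GroundTruth:
    """Generating parameters plus the directions the pipeline should recover."""

    spec_cds: dict | None = None
    spec_other: dict | None = None
    expected_genre_effect_sign: int = 0  # sign of (other - cds) discrimination
    expected_nominal_proportion_order: str = ""
    note: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def preset(name: str, seed: int = 0) -> GenreSpec:
    """Documented parameter bundles: cds_like, ads_like, null_contrast."""
    if name == "cds_like":
        return GenreSpec(
            genre="cds",
            mean_utterance_length=4.0,
            one_word_utterance_rate=0.17,
            verbless_rate=0.18,
            pp_recursion_rate=0.14,
            frame_concentration=0.6,
            nominal_density=0.75,
            causative_frame_bias=0.9,
            noncausative_frame_bias=0.9,
            transitive_frames=CDS_TRANSITIVE,
            noncausative_frames=CDS_NONCAUSATIVE,
            general_frames=CDS_GENERAL,
            verbless_frames=CDS_VERBLESS,
            lexicon=_default_lexicon(60, 20, 20, 30),
            seed=seed,
        )
    if name == "ads_like":
        return GenreSpec(
            genre="adult_conversation",
            mean_utterance_length=12.0,
            one_word_utterance_rate=0.01,
            verbless_rate=0.03,
            pp_recursion_rate=0.50,
            frame_concentration=2.5,
            nominal_density=0.40,
            causative_frame_bias=0.35,
            noncausative_frame_bias=0.35,
            transitive_frames=ADS_TRANSITIVE,
            noncausative_frames=ADS_NONCAUSATIVE,
            general_frames=ADS_GENERAL,
            verbless_frames=ADS_VERBLESS,
            lexicon=_default_lexicon(300, 60, 60, 60),
            seed=seed,
        )
    if name == "null_contrast":
        spec = preset("cds_like", seed=seed)
        spec.genre = "cds"
        spec.causative_frame_bias = 0.0
        spec.noncausative_frame_bias = 0.0
        return spec
    raise ValueError(f"unknown preset {name!r}")


def _zipf_probs(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


def _frame_probs(pool: list[tuple[Frame, float]], concentration: float) -> np.ndarray:
    base = np.array([w for _, w in pool])
    with np.errstate(over="ignore"):
        w = base ** (1.0 / concentration)
    if not np.all(np.isfinite(w)) or w.sum() == 0:
        # concentration -> 0 degenerates to the single most probable frame
        w = (base == base.max()).astype(float)
    return w / w.sum()


class _Sampler:
    """Seeded sampling machinery shared across utterances of one corpus."""

    def __init__(self, spec: GenreSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.lex_probs = {
            cls: _zipf_probs(len(words), spec.zipf_exponent)
            for cls, words in spec.lexicon.items()
        }
        self.targets = list(CAUSATIVES) + list(NONCAUSATIVES)
        self.target_probs = _zipf_probs(len(self.targets), spec.zipf_exponent)
        self.pools = {
            "transitive": (
                [f for f, _ in spec.transitive_frames],
                _frame_probs(spec.transitive_frames, spec.frame_concentration),
            ),
            "noncausative": (
                [f for f, _ in spec.noncausative_frames],
                _frame_probs(spec.noncausative_frames, spec.frame_concentration),
            ),
            "general": (
                [f for f, _ in spec.general_frames],
                _frame_probs(spec.general_frames, spec.frame_concentration),
            ),
            "verbless": (
                [f for f, _ in spec.verbless_frames],
                _frame_probs(spec.verbless_frames, spec.frame_concentration),
            ),
        }

    def word(self, cls: str) -> str:
        words = self.spec.lexicon[cls]
        return words[self.rng.choice(len(words), p=self.lex_probs[cls])]

    def pick_frame(self, pool: str) -> Frame:
        frames, probs = self.pools[pool]
        return frames[self.rng.choice(len(frames), p=probs)]

    def pick_verb(self) -> str:
        if self.rng.random() < self.spec.target_verb_rate:
            return self.targets[self.rng.choice(len(self.targets),
                                                p=self.target_probs)]
        return self.word("V2")

    def utterance(self) -> Utterance:
        spec = self.spec
        if self.rng.random() < spec.verbless_rate:
            frame = self.pick_frame("verbless")
            verb = None
        else:
            verb = self.pick_verb()
            if verb in CAUSATIVES:
                pool = ("transitive"
                        if self.rng.random() < spec.causative_frame_bias
                        else "general")
            elif verb in NONCAUSATIVES:
                pool = ("noncausative"
                        if self.rng.random() < spec.noncausative_frame_bias
                        else "general")
            else:
                pool = "general"
            frame = self.pick_frame(pool)
        tokens = []
        for cls, head, deprel in frame:
            if cls == "V":
                lemma, upos = verb, "VERB"
            elif cls == "V2":
                lemma, upos = self.word("V2"), "VERB"
            else:
                lemma, upos = self.word(cls), cls
            tokens.append(
                Token(lemma=lemma, upos=upos,
                      head=0 if head is None else head + 1, deprel=deprel)
            )
        if verb is not None and spec.pp_recursion_rate > 0:
            verb_pos = next(i for i, (cls, _, _) in enumerate(frame)
                            if cls == "V") + 1  # 1-based head index
            extensions = 0
            while extensions < 4 and self.rng.random() < spec.pp_recursion_rate:
                base = len(tokens)
                tokens.append(Token(lemma=self.word("ADP"), upos="ADP",
                                    head=verb_pos, deprel="prep"))
                tokens.append(Token(lemma=self.word("DET"), upos="DET",
                                    head=base + 3, deprel="det"))
                tokens.append(Token(lemma=self.word("NOUN"), upos="NOUN",
                                    head=base + 1, deprel="pobj"))
                extensions += 1
        return Utterance(tuple(tokens))


def generate_corpus(
    spec: GenreSpec,
    n_sessions: int = 50,
    utterances_per_session: int = 200,
    seed: int | None = None,
) -> tuple[Corpus, GroundTruth]:
    """Generate a session-organized corpus from a genre spec.

    Deterministic given the seed (``spec.seed`` unless overridden).  The
    ground-truth sidecar records the generating parameters and the contrast
    directions a correct pipeline should recover.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sampler = _Sampler(spec, rng)
    sessions = [
        Session(
            id=f"{spec.genre}-s{k:03d}",
            utterances=[sampler.utterance()
                        for _ in range(utterances_per_session)],
        )
        for k in range(n_sessions)
    ]
    corpus = Corpus(genre=spec.genre, sessions=sessions)
    truth = GroundTruth(
        spec_cds=None,
        spec_other={k: v for k, v in asdict(spec).items()
                    if not isinstance(v, (list, dict))},
        expected_genre_effect_sign=0,
        note="single-genre corpus; contrast directions are defined per pair "
             "of presets (see contrast_truth)",
    )
    return corpus, truth


def contrast_truth(spec_a: GenreSpec, spec_b: GenreSpec) -> GroundTruth:
    """Expected pipeline directions for a pair of genre specs (a = reference)."""
    bias_a = spec_a.causative_frame_bias
    bias_b = spec_b.causative_frame_bias
    sign = int(np.sign(bias_b - bias_a))  # effect of b relative to a
    return GroundTruth(
        spec_cds={k: v for k, v in asdict(spec_a).items()
                  if not isinstance(v, (list, dict))},
        spec_other={k: v for k, v in asdict(spec_b).items()
                    if not isinstance(v, (list, dict))},
        expected_genre_effect_sign=sign,
        expected_nominal_proportion_order=(
            f"{spec_a.genre} > {spec_b.genre}"
            if spec_a.nominal_density > spec_b.nominal_density
            else f"{spec_b.genre} > {spec_a.genre}"
        ),
    )
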