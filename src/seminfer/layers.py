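"""Training layers: raw utterances, word-class frames, dependency subtrees.

Four layers feed the embedding trainer:

* ``raw`` — the lemmatized utterance wrapped in start/end markers.  The
  markers let even one-word utterances ("Run!") contribute co-occurrence
  evidence about argument structure and mood.
* ``wordclass`` — the utterance with every non-verb replaced by its UPOS
  tag; verbs keep their lemmas so verb semantics stays trainable.  Markers
  are kept here too.
* ``syntax`` — one instance per minimal dependency subtree (a head plus its
  direct dependents): verbs appear as lemmas, non-verb heads as their UPOS,
  non-verb dependents as their relation labels.  No markers: subtrees are
  fragments of the utterance, not utterances.
* ``lexicon`` — the same subtrees rendered as plain lemmas, encoding the
  dependency structure implicitly through lexical adjacency.

For any layer other than ``raw``, the training stream interleaves each
utterance's raw instance with that utterance's layer instances in a seeded
random order, so the trainer processes semantics and syntax of an utterance
without a systematic order bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .corpus import Corpus, CorpusValidationError, Utterance

Layer = Literal["raw", "wordclass", "syntax", "lexicon"]
LAYERS: tuple[str, ...] = ("raw", "wordclass", "syntax", "lexicon")


@dataclass(frozen=True)
class TrainingInstance:
    items: tuple[str, ...]
    origin: str

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("training instance must be non-empty")


@dataclass(frozen=True)
class LayerConfig:
    layer: str = "raw"
    start_marker: str = "^^"
    end_marker: str = "$$"
    shuffle_seed: int = 0
    # syntax layer: additionally append non-verb dependents' lemmas after
    # their relation label (the schematic figure leaves this open)
    dependent_lemmas: bool = False

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if not self.start_marker or not self.end_marker:
            raise ValueError("boundary markers must be non-empty")
        if self.start_marker == self.end_marker:
            raise ValueError("start and end markers must be distinct")


def build_raw_instance(utt: Utterance, cfg: LayerConfig) -> TrainingInstance:
    """Lemma sequence wrapped in start/end markers."""
    return TrainingInstance(
        items=(cfg.start_marker, *utt.lemmas, cfg.end_marker), origin="raw"
    )


def build_wordclass_instance(utt: Utterance, cfg: LayerConfig) -> TrainingInstance:
    """Tag frame: UPOS for every token except verbs, which keep their lemma."""
    body = tuple(t.lemma if t.upos == "VERB" else t.upos for t in utt.tokens)
    return TrainingInstance(
        items=(cfg.start_marker, *body, cfg.end_marker), origin="wordclass"
    )


@dataclass(frozen=True)
class Subtree:
    """A dependency head with its direct dependents, in surface order."""

    head_index: int  # 0-based position of the head in the utterance
    member_indices: tuple[int, ...]  # head + dependents, surface order, 0-based


def extract_subtrees(utt: Utterance) -> list[Subtree]:
    """Minimal dependency subtrees: one per token with >=1 direct dependent.

    The number of subtrees equals the number of dependency heads in the
    utterance.  Members are listed in surface order.
    """
    dependents: dict[int, list[int]] = {}
    for i, tok in enumerate(utt.tokens):
        if tok.head > 0:
            dependents.setdefault(tok.head - 1, []).append(i)
    out = []
    for head in sorted(dependents):
        members = tuple(sorted([head, *dependents[head]]))
        out.append(Subtree(head_index=head, member_indices=members))
    return out


def _syntax_symbols(utt: Utterance, st: Subtree, cfg: LayerConfig) -> list[str]:
    items: list[str] = []
    for i in st.member_indices:
        tok = utt.tokens[i]
        if tok.upos == "VERB":
            items.append(tok.lemma)  # verbs keep lemmas in every layer
        elif i == st.head_index:
            items.append(tok.upos)
        else:
            items.append(tok.deprel)
            if cfg.dependent_lemmas:
                items.append(tok.lemma)
    return items


def build_syntax_instances(
    utt: Utterance, cfg: LayerConfig | None = None
) -> list[TrainingInstance]:
    """Relation-tag rendering of each minimal subtree, surface order, no markers."""
    cfg = cfg or LayerConfig(layer="syntax")
    return [
        TrainingInstance(items=tuple(_syntax_symbols(utt, st, cfg)), origin="syntax")
        for st in extract_subtrees(utt)
    ]


def build_lexicon_instances(utt: Utterance) -> list[TrainingInstance]:
    """Lemma rendering of each minimal subtree, surface order, no markers."""
    return [
        TrainingInstance(
            items=tuple(utt.tokens[i].lemma for i in st.member_indices),
            origin="lexicon",
        )
        for st in extract_subtrees(utt)
    ]


def _layer_instances(utt: Utterance, cfg: LayerConfig) -> list[TrainingInstance]:
    if cfg.layer == "wordclass":
        return [build_wordclass_instance(utt, cfg)]
    if cfg.layer == "syntax":
        return build_syntax_instances(utt, cfg)
    if cfg.layer == "lexicon":
        return build_lexicon_instances(utt)
    raise ValueError(cfg.layer)


def assemble_training_stream(
    corpus: Corpus, cfg: LayerConfig
) -> list[TrainingInstance]:
    """Build the full training stream for one layer.

    ``raw``: one marked raw instance per utterance, corpus order preserved.
    Other layers: per utterance, the raw instance and the utterance's layer
    instances are shuffled together (seeded), then utterance bundles are
    concatenated in corpus order.  Deterministic given ``cfg.shuffle_seed``.
    """
    for utt in corpus:
        for t in utt.tokens:
            if t.lemma in (cfg.start_marker, cfg.end_marker):
                raise CorpusValidationError(
                    f"lemma {t.lemma!r} collides with a boundary marker"
                )
    if cfg.layer == "raw":
        return [build_raw_instance(u, cfg) for u in corpus]
    rng = np.random.default_rng(cfg.shuffle_seed)
    stream: list[TrainingInstance] = []
    for utt in corpus:
        bundle = [build_raw_instance(utt, cfg), *_layer_instances(utt, cfg)]
        order = rng.permutation(len(bundle))
        stream.extend(bundle[i] for i in order)
    return stream
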