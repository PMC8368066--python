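"""Session-organized annotated corpora: CoNLL-U I/O, token-budget sampling, summary stats.

A corpus is a list of sessions (recording sessions / documents), each a list
of utterances, each a list of tokens carrying a lowercased lemma, a universal
word-class tag (UPOS), and a dependency arc (1-based head index within the
utterance, 0 for the root, plus a relation label).

The interchange format is standard 10-column CoNLL-U with session boundaries
marked by ``# newdoc id = <session-id>`` comment lines.  Only the fields the
pipeline consumes (lemma, UPOS, head, deprel) are stored; the FORM column is
filled with the lemma on write because training operates on lemmatized text
exclusively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

# Utterance-boundary markers are reserved symbols in the vocabulary namespace;
# they may never occur as lemmas in a corpus.
RESERVED_MARKERS = ("^^", "$$")


class CorpusValidationError(ValueError):
    """Raised when an input violates the corpus data model."""


class ConlluParseError(ValueError):
    """Raised on malformed CoNLL-U input; message names the offending line."""


@dataclass(frozen=True)
class Token:
    lemma: str
    upos: str
    head: int  # 1-based index of the head within the utterance; 0 = root
    deprel: str

    def __post_init__(self) -> None:
        if not self.lemma:
            raise CorpusValidationError("token lemma must be non-empty")
        if self.head < 0:
            raise CorpusValidationError(f"negative head index {self.head}")


@dataclass(frozen=True)
class Utterance:
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if n < 1:
            raise CorpusValidationError("utterance must contain at least one token")
        roots = [i for i, t in enumerate(self.tokens) if t.head == 0]
        if len(roots) != 1:
            raise CorpusValidationError(
                f"utterance must have exactly one root, found {len(roots)}"
            )
        for i, t in enumerate(self.tokens, start=1):
            if t.head > n:
                raise CorpusValidationError(
                    f"head index {t.head} out of range for utterance of length {n}"
                )
            if t.head == i:
                raise CorpusValidationError(f"token {i} is its own head")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def lemmas(self) -> list[str]:
        return [t.lemma for t in self.tokens]


@dataclass
class Session:
    id: str
    utterances: list[Utterance] = field(default_factory=list)

    @property
    def token_count(self) -> int:
        return sum(len(u) for u in self.utterances)


@dataclass
class Corpus:
    genre: str = "cds"
    sessions: list[Session] = field(default_factory=list)

    def __iter__(self) -> Iterator[Utterance]:
        for s in self.sessions:
            yield from s.utterances

    @property
    def utterances(self) -> list[Utterance]:
        return [u for u in self]

    @property
    def token_count(self) -> int:
        return sum(s.token_count for s in self.sessions)


def _make_utterance(rows: list[tuple[int, str, str, int, str]],
                    sent_label: str) -> Utterance:
    try:
        return Utterance(tuple(Token(lemma=l, upos=u, head=h, deprel=d)
                               for _, l, u, h, d in rows))
    except CorpusValidationError as e:
        raise CorpusValidationError(f"sentence {sent_label}: {e}") from e


def read_conllu(path, genre: str = "cds") -> Corpus:
    """Read a session-organized corpus from a CoNLL-U file.

    Session boundaries are ``# newdoc id = <id>`` comments; sentences before
    any such comment go into a session with id ``"0"``.  Multiword-token
    ranges (ids like ``3-4``) and empty nodes (``3.1``) are skipped.  The
    LEMMA column is the stored lemma; reserved utterance markers occurring as
    lemmas are rejected.
    """
    sessions: list[Session] = []
    current: Session | None = None
    rows: list[tuple[int, str, str, int, str]] = []
    sent_id = "?"
    n_sent = 0

    def flush() -> None:
        nonlocal rows, current, n_sent
        if not rows:
            return
        if current is None:
            current = Session(id="0")
            sessions.append(current)
        n_sent += 1
        current.utterances.append(_make_utterance(rows, sent_id))
        rows = []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                comment = line[1:].strip()
                if comment.startswith("newdoc"):
                    flush()
                    _, _, value = comment.partition("=")
                    current = Session(id=value.strip() or str(len(sessions)))
                    sessions.append(current)
                elif comment.startswith("sent_id"):
                    sent_id = comment.partition("=")[2].strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ConlluParseError(
                    f"{path}: line {lineno}: expected 10 tab-separated columns, "
                    f"got {len(cols)}"
                )
            tok_id, _form, lemma, upos, _, _, head, deprel, _, _ = cols
            if "-" in tok_id or "." in tok_id:  # multiword range / empty node
                continue
            try:
                idx = int(tok_id)
                head_i = int(head)
            except ValueError as e:
                raise ConlluParseError(
                    f"{path}: line {lineno}: non-integer ID/HEAD field"
                ) from e
            if lemma in RESERVED_MARKERS:
                raise CorpusValidationError(
                    f"{path}: line {lineno}: lemma collides with reserved "
                    f"utterance marker {lemma!r}"
                )
            rows.append((idx, lemma, upos, head_i, deprel))
    flush()
    return Corpus(genre=genre, sessions=sessions)


def write_conllu(corpus: Corpus, path) -> None:
    """Write a corpus as CoNLL-U (UTF-8, LF), one ``# newdoc id`` per session.

    The FORM column repeats the lemma: this pipeline stores lemmatized text
    only, and a filled FORM keeps the file valid for third-party tools.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        sent_no = 0
        for session in corpus.sessions:
            fh.write(f"# newdoc id = {session.id}\n")
            for utt in session.utterances:
                sent_no += 1
                fh.write(f"# sent_id = {sent_no}\n")
                for i, t in enumerate(utt.tokens, start=1):
                    fh.write(
                        f"{i}\t{t.lemma}\t{t.lemma}\t{t.upos}\t_\t_\t"
                        f"{t.head}\t{t.deprel}\t_\t_\n"
                    )
                fh.write("\n")


def sample_to_token_budget(corpus: Corpus, budget: int, seed: int) -> Corpus:
    """Draw whole sessions uniformly at random until a token budget is met.

    Sessions are taken one at a time, with all their utterances, never split.
    Drawing stops at the first session whose inclusion would overshoot the
    budget; that session is kept iff the total with it is closer to the
    budget than the total without it.  Deterministic given ``seed``.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    if not corpus.sessions:
        raise CorpusValidationError("cannot sample from a corpus with no sessions")
    if corpus.token_count <= budget:
        return Corpus(genre=corpus.genre, sessions=list(corpus.sessions))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus.sessions))
    chosen: list[Session] = []
    total = 0
    for idx in order:
        session = corpus.sessions[idx]
        new_total = total + session.token_count
        if new_total > budget:
            if abs(new_total - budget) < abs(total - budget):
                chosen.append(session)
            break
        chosen.append(session)
        total = new_total
        if total == budget:
            break
    return Corpus(genre=corpus.genre, sessions=chosen)


def corpus_stats(corpus: Corpus) -> dict:
    """Token/utterance counts, mean length of utterances (MLU), one-word
    utterance proportion, and lemma type count."""
    lengths = [len(u) for u in corpus]
    if not lengths:
        raise CorpusValidationError("corpus_stats requires a non-empty corpus")
    types = {t.lemma for u in corpus for t in u.tokens}
    n_utt = len(lengths)
    return {
        "token_count": int(sum(lengths)),
        "utterance_count": n_utt,
        "mlu": float(sum(lengths) / n_utt),
        "one_word_proportion": float(sum(1 for n in lengths if n == 1) / n_utt),
        "type_count": len(types),
    }
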