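"""Skip-gram with negative sampling (SGNS), implemented from first principles.

The trainer learns one input vector per word type by predicting context words
within a symmetric window around each target token, against ``k`` noise words
drawn from the unigram distribution raised to 3/4.  Context order is
dissolved: every word within the window is an equivalent (center, context)
pair, carrying no positional information, and windows never cross instance
boundaries.  With window size 1 a window therefore spans exactly three
tokens: the target plus one word on each side.

For one pair with center vector ``v``, context output-vector ``u`` and noise
output-vectors ``u_1..u_k`` the loss is::

    L = -log sigma(u . v) - sum_k log sigma(-u_k . v)

optimized by mini-batch SGD with a linearly decaying learning rate.  The
reference path is single-threaded NumPy and bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .layers import TrainingInstance


class OOVError(KeyError):
    """Requested word is not in the model vocabulary."""


@dataclass
class Vocab:
    id_of: dict[str, int]
    count_of: dict[str, int]
    min_count: int = 1

    def __post_init__(self) -> None:
        ids = sorted(self.id_of.values())
        if ids != list(range(len(ids))):
            raise ValueError("vocabulary ids must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.id_of)

    def __contains__(self, word: str) -> bool:
        return word in self.id_of

    @property
    def words(self) -> list[str]:
        out = [""] * len(self.id_of)
        for w, i in self.id_of.items():
            out[i] = w
        return out


def build_vocab(stream: Sequence[TrainingInstance], min_count: int = 1) -> Vocab:
    """Count types over the stream; keep those with frequency >= min_count.

    Boundary markers and tag symbols are ordinary types: everything the
    trainer sees is just a symbol.
    """
    if not stream:
        raise ValueError("cannot build a vocabulary from an empty stream")
    counts: dict[str, int] = {}
    for inst in stream:
        for item in inst.items:
            counts[item] = counts.get(item, 0) + 1
    kept = {w: c for w, c in counts.items() if c >= min_count}
    if not kept:
        raise ValueError("no type reaches min_count; vocabulary would be empty")
    # deterministic id order: frequency desc, then lexicographic
    ordered = sorted(kept, key=lambda w: (-kept[w], w))
    return Vocab(
        id_of={w: i for i, w in enumerate(ordered)},
        count_of={w: kept[w] for w in ordered},
        min_count=min_count,
    )


def generate_pairs(
    instance: TrainingInstance, window: int
) -> list[tuple[str, str]]:
    """All (center, context) pairs with |i - j| <= window, i != j.

    Order within the window is dissolved: the pair list is the only output,
    with no positional feature attached.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    items = instance.items
    n = len(items)
    pairs = []
    for i in range(n):
        for j in range(max(0, i - window), min(n, i + window + 1)):
            if j != i:
                pairs.append((items[i], items[j]))
    return pairs


@dataclass
class EmbeddingModel:
    vocab: Vocab
    vectors: np.ndarray  # input-side embeddings, shape (V, dim)
    out_vectors: np.ndarray  # output-side (context) embeddings
    window: int
    dim: int
    epochs: int
    seed: int
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.window <= 6):
            raise ValueError("window must lie in [1, 6]")
        if not np.all(np.isfinite(self.vectors)):
            raise FloatingPointError("non-finite values in embedding matrix")

    def vector(self, word: str) -> np.ndarray:
        return vector(self, word)


def vector(model: EmbeddingModel, word: str) -> np.ndarray:
    """Input-side embedding row; OOV words raise, never a silent zero."""
    if word not in model.vocab:
        raise OOVError(f"word {word!r} not in model vocabulary")
    return model.vectors[model.vocab.id_of[word]]


def pair_loss_and_grad(
    v: np.ndarray, u_pos: np.ndarray, u_neg: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and analytic gradients for one (center, context, negatives) triple.

    Returns (loss, dL/dv, dL/du_pos, dL/dU_neg).  Exposed separately so the
    gradient can be verified against central differences.
    """
    from scipy.special import expit

    s_pos = expit(float(v @ u_pos))
    s_neg = expit(u_neg @ v)
    eps = 1e-12
    loss = -np.log(s_pos + eps) - float(np.sum(np.log(1.0 - s_neg + eps)))
    g_pos = s_pos - 1.0
    dv = g_pos * u_pos + s_neg @ u_neg
    du_pos = g_pos * v
    du_neg = s_neg[:, None] * v[None, :]
    return loss, dv, du_pos, du_neg


def _encode_pairs(
    stream: Sequence[TrainingInstance], vocab: Vocab, window: int
) -> tuple[np.ndarray, np.ndarray]:
    id_of = vocab.id_of
    centers: list[int] = []
    contexts: list[int] = []
    for inst in stream:
        ids = [id_of[w] for w in inst.items if w in id_of]
        n = len(ids)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(ids[i])
                    contexts.append(ids[j])
    return (
        np.asarray(centers, dtype=np.int64),
        np.asarray(contexts, dtype=np.int64),
    )


def _sgns_sgd(centers, contexts, W_in, W_out, noise_cdf, epochs, negatives,
              lr0, lr_min, seed):
    """Sequential SGD over shuffled (center, context) pairs.

    Classic word2vec skip-gram updates, one pair at a time, with a linearly
    decaying learning rate.  Random numbers (epoch shuffles, negative
    draws) come from an internal xorshift64* generator so the numba-compiled
    and the pure-python execution of this exact function are bit-identical
    given the seed.
    """
    n_pairs = centers.shape[0]
    dim = W_in.shape[1]
    total = epochs * n_pairs
    loss_trace = np.zeros(epochs)
    order = np.arange(n_pairs)
    state = (np.uint64(seed) * np.uint64(2654435761)
             + np.uint64(1442695040888963407))
    mult = np.uint64(2685821657736338717)
    inv64 = 1.0 / 18446744073709551616.0
    step = 0
    for epoch in range(epochs):
        for i in range(n_pairs - 1, 0, -1):  # Fisher-Yates shuffle
            state ^= state >> np.uint64(12)
            state ^= state << np.uint64(25)
            state ^= state >> np.uint64(27)
            u = np.float64(state * mult) * inv64
            j = int(u * (i + 1))
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        loss = 0.0
        for pi in range(n_pairs):
            idx = order[pi]
            alpha = lr0 - (lr0 - lr_min) * (step / max(1, total - 1))
            step += 1
            c = centers[idx]
            o = contexts[idx]
            v = W_in[c]
            dv = np.zeros(dim)
            for t in range(negatives + 1):
                if t == 0:
                    target = o
                    label = 1.0
                else:
                    state ^= state >> np.uint64(12)
                    state ^= state << np.uint64(25)
                    state ^= state >> np.uint64(27)
                    u = np.float64(state * mult) * inv64
                    target = int(np.searchsorted(noise_cdf, u))
                    label = 0.0
                uvec = W_out[target]
                x = 0.0
                for d in range(dim):
                    x += v[d] * uvec[d]
                x = min(30.0, max(-30.0, x))
                s = 1.0 / (1.0 + np.exp(-x))
                if label == 1.0:
                    loss -= np.log(s + 1e-12)
                else:
                    loss -= np.log(1.0 - s + 1e-12)
                g = (s - label) * alpha
                for d in range(dim):
                    dv[d] += (s - label) * uvec[d]
                    uvec[d] -= g * v[d]
            for d in range(dim):
                v[d] -= alpha * dv[d]
        loss_trace[epoch] = loss / n_pairs
    return loss_trace


try:  # compiled fast path; same arithmetic and random stream
    from numba import njit as _njit

    _sgns_sgd_fast = _njit(cache=False, fastmath=False)(_sgns_sgd)
except ImportError:  # pragma: no cover - numba is a soft dependency
    _sgns_sgd_fast = None


def train(
    stream: Sequence[TrainingInstance],
    window: int = 1,
    dim: int = 200,
    epochs: int = 100,
    negatives: int = 5,
    seed: int = 0,
    min_count: int = 1,
    lr: float = 0.025,
    lr_min: float = 1e-4,
) -> EmbeddingModel:
    """Train SGNS embeddings over a stream of training instances.

    Pairs are visited one at a time in a seeded random order each epoch
    (classic word2vec SGD); noise words are drawn from unigram^0.75; no
    frequent-word subsampling is applied (repetitive frames are signal
    here, not noise).  Single-threaded and bit-deterministic given ``seed``.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    vocab = build_vocab(stream, min_count=min_count)
    V = len(vocab)
    rng = np.random.default_rng(seed)

    counts = np.array([vocab.count_of[w] for w in vocab.words], dtype=np.float64)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0

    centers, contexts = _encode_pairs(stream, vocab, window)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("stream yields no training pairs at this window")

    W_in = (rng.random((V, dim), dtype=np.float64) - 0.5) / dim
    W_out = np.zeros((V, dim), dtype=np.float64)

    kernel = _sgns_sgd_fast if _sgns_sgd_fast is not None else _sgns_sgd
    loss_trace = kernel(centers, contexts, W_in, W_out, noise_cdf,
                        epochs, negatives, lr, lr_min, seed)
    if not np.all(np.isfinite(loss_trace)):
        raise FloatingPointError("non-finite training loss")

    return EmbeddingModel(
        vocab=vocab,
        vectors=W_in,
        out_vectors=W_out,
        window=window,
        dim=dim,
        epochs=epochs,
        seed=seed,
        loss_trace=[float(x) for x in loss_trace],
    )


def save_word2vec(model: EmbeddingModel, path) -> None:
    """Serialize input vectors in the word2vec text format ("V D" header)."""
    words = model.vocab.words
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(words)} {model.dim}\n")
        for i, w in enumerate(words):
            vec = " ".join(repr(float(x)) for x in model.vectors[i])
            fh.write(f"{w} {vec}\n")


def load_word2vec(path, window: int = 1) -> EmbeddingModel:
    """Load a word2vec text file as a (training-metadata-free) model."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        V, dim = int(header[0]), int(header[1])
        words, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            words.append(parts[0])
            rows.append([float(x) for x in parts[1 : dim + 1]])
    if len(words) != V:
        raise ValueError(f"header promised {V} rows, file has {len(words)}")
    vectors = np.asarray(rows, dtype=np.float64)
    vocab = Vocab(
        id_of={w: i for i, w in enumerate(words)},
        count_of={w: 1 for w in words},
        min_count=1,
    )
    return EmbeddingModel(
        vocab=vocab,
        vectors=vectors,
        out_vectors=np.zeros_like(vectors),
        window=window,
        dim=dim,
        epochs=1,
        seed=0,
        loss_trace=[0.0],
    )
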