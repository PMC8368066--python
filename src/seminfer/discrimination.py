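"""Causative-discrimination measures on trained embeddings.

The discrimination statistic asks whether causative verbs (verbs entailing
that an agent changes the state of a patient, e.g. *break*, *open*) sit
farther from non-causative verbs in embedding space than an average pair of
frequent verbs does.  It is built from three pieces:

1. pairwise cosine distances between a fixed list of 23 causatives and 9
   non-causatives (207 pairs at full vocabulary coverage),
2. a chance baseline: the mean cosine distance over random pairs of frequent
   verbs (default 10000 pairs, frequency floor 10),
3. above-baseline scores: distance minus baseline, positive meaning
   better-than-chance discrimination.

A neighbor-joining clustering of the verb-by-verb distance matrix provides a
qualitative view of which verbs group together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Corpus
from .sgns import EmbeddingModel, vector

CAUSATIVES: tuple[str, ...] = (
    "begin", "boil", "break", "burn", "change", "close", "destroy", "dry",
    "fill", "finish", "freeze", "gather", "kill", "lose", "melt", "open",
    "raise", "roll", "sink", "spread", "stop", "teach", "turn",
)
NONCAUSATIVES: tuple[str, ...] = (
    "die", "go", "look", "talk", "want", "like", "think", "say", "take",
)


@dataclass(frozen=True)
class VerbSets:
    causatives: tuple[str, ...] = CAUSATIVES
    noncausatives: tuple[str, ...] = NONCAUSATIVES

    def __post_init__(self) -> None:
        if set(self.causatives) & set(self.noncausatives):
            raise ValueError("causative and non-causative sets must be disjoint")


@dataclass(frozen=True)
class BaselineEstimate:
    mean_distance: float
    n_pairs: int = 10000
    frequent_floor: int = 10
    seed: int = 0
    genre: str | None = None
    window: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_distance <= 2.0):
            raise ValueError("mean cosine distance must lie in [0, 2]")


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(theta) between two vectors; ranges over [0, 2]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance is undefined for a zero vector")
    d = 1.0 - float(u @ v) / (nu * nv)
    # clip float noise at the boundaries, never real values
    return float(min(2.0, max(0.0, d)))


def pairwise_distances(
    model: EmbeddingModel,
    sets: VerbSets | None = None,
    genre: str | None = None,
    window: int | None = None,
    layer: str | None = None,
) -> pd.DataFrame:
    """Cosine distance for every in-vocabulary (causative, non-causative) pair.

    Verbs absent from the model vocabulary are dropped with a warning; full
    coverage of the default lists gives 23 x 9 = 207 rows.
    """
    sets = sets or VerbSets()
    caus = [w for w in sets.causatives if w in model.vocab]
    nonc = [w for w in sets.noncausatives if w in model.vocab]
    missing = [w for w in (*sets.causatives, *sets.noncausatives)
               if w not in model.vocab]
    if missing:
        warnings.warn(
            f"{len(missing)} target verb(s) missing from vocabulary: "
            + ", ".join(missing),
            stacklevel=2,
        )
    if not caus or not nonc:
        raise ValueError("no causative/non-causative pair is covered by the model")
    rows = [
        {
            "causative": ci,
            "noncausative": nj,
            "distance": cosine_distance(vector(model, ci), vector(model, nj)),
        }
        for ci in caus
        for nj in nonc
    ]
    table = pd.DataFrame(rows)
    table["genre"] = genre
    table["window"] = window if window is not None else model.window
    table["layer"] = layer
    return table


def frequent_verbs(corpus: Corpus, floor: int = 10) -> set[str]:
    """Lemmas with at least ``floor`` VERB-tagged occurrences in the corpus."""
    counts: dict[str, int] = {}
    for utt in corpus:
        for tok in utt.tokens:
            if tok.upos == "VERB":
                counts[tok.lemma] = counts.get(tok.lemma, 0) + 1
    return {w for w, c in counts.items() if c >= floor}


def estimate_baseline(
    model: EmbeddingModel,
    verbs: set[str],
    n_pairs: int = 10000,
    seed: int = 0,
    frequent_floor: int = 10,
    genre: str | None = None,
    window: int | None = None,
) -> BaselineEstimate:
    """Mean cosine distance over random unordered pairs of distinct verbs.

    Pairs are sampled uniformly with replacement across pairs; only verbs in
    the model vocabulary are eligible.  Deterministic given ``seed``.
    """
    eligible = sorted(v for v in verbs if v in model.vocab)
    if len(eligible) < 2:
        raise ValueError("need at least 2 in-vocabulary verbs for a baseline")
    rng = np.random.default_rng(seed)
    nv = len(eligible)
    vecs = np.stack([vector(model, v) for v in eligible])
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm verb vector encountered")
    unit = vecs / norms[:, None]
    # uniform over unordered pairs of distinct verbs, with replacement
    # across the n_pairs draws
    i = rng.integers(0, nv, size=n_pairs)
    j = rng.integers(0, nv - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)
    d = 1.0 - np.einsum("pd,pd->p", unit[i], unit[j])
    d = np.clip(d, 0.0, 2.0)
    return BaselineEstimate(
        mean_distance=float(d.mean()),
        n_pairs=n_pairs,
        frequent_floor=frequent_floor,
        seed=seed,
        genre=genre,
        window=window if window is not None else model.window,
    )


def above_baseline(
    table: pd.DataFrame,
    baseline: BaselineEstimate,
    check_window: bool = True,
) -> pd.DataFrame:
    """Distance minus baseline per pair; positive = better than chance.

    The baseline must come from the matching window (and, per the study
    design, the appropriate reference model); a window mismatch errors unless
    explicitly disabled.
    """
    if check_window and baseline.window is not None:
        windows = set(table["window"].unique())
        if windows != {baseline.window}:
            raise ValueError(
                f"baseline window {baseline.window} does not match table "
                f"window(s) {sorted(windows)}"
            )
    out = table.copy()
    out["above_baseline"] = out["distance"] - baseline.mean_distance
    out["baseline"] = baseline.mean_distance
    return out


# --- neighbor joining ------------------------------------------------------


def neighbor_joining(
    dist: np.ndarray, labels: list[str] | None = None
) -> str:
    """Saitou-Nei neighbor joining on a distance matrix; returns Newick.

    Ties on the Q criterion break to the lowest (i, j) index pair.  Negative
    branch lengths are retained (a property of NJ on non-additive input) and
    reported with a warning rather than clamped.
    """
    D = np.array(dist, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count must match matrix size")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes = list(labels)  # newick fragment per active node
    saw_negative = False

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    if n == 2:
        return f"({nodes[0]}:{fmt(D[0, 1] / 2)},{nodes[1]}:{fmt(D[0, 1] / 2)});"

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index (i, j) pair on ties: argmin of the upper triangle in
        # row-major order
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < best[0] - 1e-12:
                    best = (Q[i, j], i, j)
        _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            saw_negative = True
        merged = f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})"
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [merged]

    a, b, c = range(3)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    if min(la, lb, lc) < 0:
        saw_negative = True
    if saw_negative:
        warnings.warn("neighbor joining produced negative branch length(s)",
                      stacklevel=2)
    return (
        f"({nodes[a]}:{fmt(la)},{nodes[b]}:{fmt(lb)},{nodes[c]}:{fmt(lc)});"
    )


def verb_distance_matrix(
    model: EmbeddingModel, verbs: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Symmetric cosine-distance matrix over the in-vocabulary subset of verbs."""
    present = [v for v in verbs if v in model.vocab]
    vecs = [vector(model, v) for v in present]
    m = len(present)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = cosine_distance(vecs[i], vecs[j])
    return D, present
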