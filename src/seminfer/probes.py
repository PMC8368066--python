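"""Distributional probes of verbal constructions.

Three diagnostics characterize what surrounds verbs in a genre, per window
size ``w`` (tokens on each side of the verb, truncated at utterance
boundaries):

(i)   nominal proportion — the mean, over verbal constructions, of the share
      of context tokens that are nominals (NOUN, PROPN, PRON);
(ii)  nominal entropy — Shannon entropy (bits) of the nominal lemmas
      occurring in verb contexts;
(iii) construction entropy — Shannon entropy (bits) of the word-class frame
      types around verbs, e.g. "PRON verb NOUN" at window 1.

Each is reported with a bootstrap mean and SD: 1000 resampled units
(constructions for (i) and (iii), nominal tokens for (ii)) per iteration,
1000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Token

NOMINAL_TAGS = frozenset({"NOUN", "PROPN", "PRON"})
STATISTICS = ("nominal_proportion", "nominal_entropy", "construction_entropy")


@dataclass(frozen=True)
class VerbalConstruction:
    verb: str
    left: tuple[Token, ...]
    right: tuple[Token, ...]

    @property
    def context(self) -> tuple[Token, ...]:
        return self.left + self.right


@dataclass(frozen=True)
class ProbeResult:
    statistic: str
    window: int
    genre: str
    point: float
    bootstrap_sd: float
    n_boot_units: int = 1000
    n_iterations: int = 1000
    seed: int = 0


def extract_constructions(corpus: Corpus, window: int) -> list[VerbalConstruction]:
    """One construction per VERB token; contexts truncate at utterance edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out = []
    for utt in corpus:
        toks = utt.tokens
        for i, tok in enumerate(toks):
            if tok.upos == "VERB":
                out.append(
                    VerbalConstruction(
                        verb=tok.lemma,
                        left=tuple(toks[max(0, i - window) : i]),
                        right=tuple(toks[i + 1 : i + 1 + window]),
                    )
                )
    return out


def nominal_proportion(constructions: list[VerbalConstruction]) -> float:
    """Mean per-construction share of nominal context tokens.

    Constructions with an empty context (one-word verb utterances) have no
    defined ratio and are excluded from the average.
    """
    ratios = [
        sum(t.upos in NOMINAL_TAGS for t in c.context) / len(c.context)
        for c in constructions
        if c.context
    ]
    if not ratios:
        raise ValueError("no construction has a non-empty context")
    return float(np.mean(ratios))


def shannon_entropy(items: list) -> float:
    """Shannon entropy in bits of the empirical distribution of the items."""
    if not items:
        raise ValueError("entropy of an empty sample is undefined")
    _, counts = np.unique(np.asarray(items, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def construction_signature(c: VerbalConstruction) -> str:
    """Word-class frame string with the verb abstracted to "verb"."""
    parts = [t.upos for t in c.left] + ["verb"] + [t.upos for t in c.right]
    return " ".join(parts)


def nominal_tokens(constructions: list[VerbalConstruction]) -> list[str]:
    """Lemmas of all nominal tokens occurring in verb contexts."""
    return [
        t.lemma for c in constructions for t in c.context if t.upos in NOMINAL_TAGS
    ]


def _statistic_units(
    constructions: list[VerbalConstruction], statistic: str
) -> list:
    if statistic == "nominal_proportion":
        return [c for c in constructions if c.context]
    if statistic == "nominal_entropy":
        return nominal_tokens(constructions)
    if statistic == "construction_entropy":
        return [construction_signature(c) for c in constructions]
    raise ValueError(f"unknown statistic {statistic!r}")


def probe_point(corpus: Corpus, window: int, statistic: str) -> float:
    """Full-sample (non-bootstrapped) value of a probe statistic."""
    units = _statistic_units(extract_constructions(corpus, window), statistic)
    if statistic == "nominal_proportion":
        return nominal_proportion(units)
    return shannon_entropy(units)


def bootstrap_probe(
    corpus: Corpus,
    window: int,
    statistic: str,
    n_units: int = 1000,
    n_iter: int = 1000,
    seed: int = 0,
    genre: str | None = None,
) -> ProbeResult:
    """Bootstrap mean and SD of one probe statistic.

    Per iteration, ``n_units`` units are resampled with replacement —
    verbal constructions for the nominal proportion and the construction
    entropy, nominal tokens for the nominal entropy — and the statistic is
    computed on the resample.
    """
    constructions = extract_constructions(corpus, window)
    units = _statistic_units(constructions, statistic)
    if not units:
        raise ValueError(f"no units to resample for {statistic!r}")
    rng = np.random.default_rng(seed)
    n = len(units)
    values = np.empty(n_iter)
    if statistic == "nominal_proportion":
        # per-construction ratios; a resample's statistic is their mean
        ratios = np.array(
            [sum(t.upos in NOMINAL_TAGS for t in c.context) / len(c.context)
             for c in units]
        )
        for it in range(n_iter):
            values[it] = ratios[rng.integers(0, n, size=n_units)].mean()
    else:
        # integer-code the symbols once; entropy of a resample via bincount
        _, codes = np.unique(np.asarray(units, dtype=object),
                             return_inverse=True)
        k = codes.max() + 1
        for it in range(n_iter):
            counts = np.bincount(codes[rng.integers(0, n, size=n_units)],
                                 minlength=k)
            p = counts[counts > 0] / n_units
            values[it] = -(p * np.log2(p)).sum()
    return ProbeResult(
        statistic=statistic,
        window=window,
        genre=genre or corpus.genre,
        point=float(values.mean()),
        bootstrap_sd=float(values.std(ddof=1)),
        n_boot_units=n_units,
        n_iterations=n_iter,
        seed=seed,
    )
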