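"""End-to-end orchestration of the two studies.

Study 1: does raw-utterance co-occurrence support causative discrimination,
and does that differ by genre?  Per genre and window, a raw-layer embedding
model is trained and causative/non-causative distances are computed; the
baseline is the mean random-frequent-verb-pair distance in the reference
genre's (cds) raw model for that window; per window, a hierarchical model
regresses the above-baseline distance on genre.

Study 2: does adding word-class or dependency-syntax information help?  Per
genre, window and layer, a model is trained on the layer's stream; baselines
come from the same genre-and-window raw model; per genre and window, a
hierarchical model regresses the above-baseline distance on layer, and
Pseudo-BMA+ weights compare the layer model against an intercept-only null.

Every stage's seed is derived deterministically from the master seed and the
stage coordinates, so no seed is ever reused across stages and any artifact
can be regenerated from the config alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import bayes, discrimination, layers, sgns, synth
from .corpus import Corpus

PRESET_OF_GENRE = {
    "cds": "cds_like",
    "adult_conversation": "ads_like",
    "written": "ads_like",
    "null": "null_contrast",
}


def stage_seed(master_seed: int, *parts) -> int:
    """Deterministic per-stage seed below 2^31, from master seed + stage name."""
    key = ":".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    genres: list[str] = field(default_factory=lambda: ["cds", "adult_conversation"])
    windows: list[int] = field(default_factory=lambda: [1])
    layers: list[str] = field(default_factory=lambda: ["raw", "wordclass", "syntax"])
    reference_genre: str = "cds"
    # embedding hyperparameters (headline settings: dim 200, 100 epochs;
    # desk-scale defaults are smaller, see docs/methods.md)
    dim: int = 200
    epochs: int = 100
    negatives: int = 5
    min_count: int = 1
    # baseline settings
    baseline_pairs: int = 10000
    frequent_floor: int = 10
    # sampler settings
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    # synthetic corpora
    n_sessions: int = 50
    utterances_per_session: int = 200
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = [w for w in self.windows if not 1 <= w <= 6]
        if bad:
            raise ValueError(f"windows must lie in 1..6, got {bad}")
        bad = [l for l in self.layers if l not in layers.LAYERS]
        if bad:
            raise ValueError(f"unknown layers {bad}")
        if "raw" not in self.layers:
            raise ValueError("'raw' layer is required (it anchors the baselines)")


def _get_corpora(config: PipelineConfig, corpora: dict | None) -> dict[str, Corpus]:
    if corpora is not None:
        missing = [g for g in config.genres if g not in corpora]
        if missing:
            raise ValueError(f"no corpus supplied for genre(s) {missing}")
        return corpora
    out = {}
    for genre in config.genres:
        spec = synth.preset(PRESET_OF_GENRE.get(genre, "ads_like"))
        spec.genre = genre
        corpus, _ = synth.generate_corpus(
            spec,
            n_sessions=config.n_sessions,
            utterances_per_session=config.utterances_per_session,
            seed=stage_seed(config.master_seed, "corpus", genre),
        )
        out[genre] = corpus
    return out


def _train_model(config, corpus, genre, window, layer):
    cfg = layers.LayerConfig(
        layer=layer,
        shuffle_seed=stage_seed(config.master_seed, "shuffle", genre, window, layer),
    )
    stream = layers.assemble_training_stream(corpus, cfg)
    return sgns.train(
        stream,
        window=window,
        dim=config.dim,
        epochs=config.epochs,
        negatives=config.negatives,
        min_count=config.min_count,
        seed=stage_seed(config.master_seed, "train", genre, window, layer),
    )


def run_study1(config: PipelineConfig, corpora: dict[str, Corpus] | None = None) -> dict:
    """Genre comparison on raw-layer models; see module docstring."""
    corpora = _get_corpora(config, corpora)
    ref = config.reference_genre
    if ref not in corpora:
        raise ValueError(f"reference genre {ref!r} has no corpus")

    manifest = {"study": 1, "config": asdict(config), "stages": []}
    models, tables = {}, {}
    for genre, corpus in corpora.items():
        for window in config.windows:
            model = _train_model(config, corpus, genre, window, "raw")
            models[genre, window] = model
            tables[genre, window] = discrimination.pairwise_distances(
                model, genre=genre, window=window, layer="raw"
            )
            manifest["stages"].append(
                {"stage": "train", "genre": genre, "window": window,
                 "layer": "raw",
                 "seed": stage_seed(config.master_seed, "train", genre, window,
                                    "raw"),
                 "final_loss": model.loss_trace[-1]}
            )

    ref_verbs = discrimination.frequent_verbs(corpora[ref], config.frequent_floor)
    baselines = {}
    for window in config.windows:
        baselines[window] = discrimination.estimate_baseline(
            models[ref, window],
            ref_verbs,
            n_pairs=config.baseline_pairs,
            frequent_floor=config.frequent_floor,
            seed=stage_seed(config.master_seed, "baseline", ref, window),
            genre=ref,
            window=window,
        )

    rows = []
    for (genre, window), table in tables.items():
        scored = discrimination.above_baseline(table, baselines[window])
        scored["genre"] = genre
        rows.append(scored)
    rows = pd.concat(rows, ignore_index=True)
    rows = rows.rename(columns={"above_baseline": "response",
                                "causative": "caus", "noncausative": "noncaus"})

    fits = {}
    for window in config.windows:
        sub = rows[rows["window"] == window]
        fits[window] = bayes.fit_hierarchical(
            sub,
            predictor="genre",
            chains=config.chains,
            draws=config.draws,
            warmup=config.warmup,
            seed=stage_seed(config.master_seed, "fit", "study1", window),
            reference=ref,
            name=f"study1_w{window}",
        )

    bundle = {"models": models, "distances": tables, "baselines": baselines,
              "rows": rows, "fits": fits, "manifest": manifest}
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir), study=1)
    return bundle


def run_study2(config: PipelineConfig, corpora: dict[str, Corpus] | None = None) -> dict:
    """Layer comparison within each genre and window; see module docstring."""
    corpora = _get_corpora(config, corpora)
    manifest = {"study": 2, "config": asdict(config), "stages": []}
    tables, baselines = {}, {}
    models = {}
    for genre, corpus in corpora.items():
        verbs = discrimination.frequent_verbs(corpus, config.frequent_floor)
        for window in config.windows:
            for layer in config.layers:
                model = _train_model(config, corpus, genre, window, layer)
                models[genre, window, layer] = model
                tables[genre, window, layer] = discrimination.pairwise_distances(
                    model, genre=genre, window=window, layer=layer
                )
            baselines[genre, window] = discrimination.estimate_baseline(
                models[genre, window, "raw"],
                verbs,
                n_pairs=config.baseline_pairs,
                frequent_floor=config.frequent_floor,
                seed=stage_seed(config.master_seed, "baseline2", genre, window),
                genre=genre,
                window=window,
            )
            manifest["stages"].append(
                {"stage": "baseline", "genre": genre, "window": window,
                 "mean": baselines[genre, window].mean_distance}
            )

    rows = []
    for (genre, window, layer), table in tables.items():
        scored = discrimination.above_baseline(table, baselines[genre, window])
        scored["genre"] = genre
        scored["layer"] = layer
        rows.append(scored)
    rows = pd.concat(rows, ignore_index=True)
    rows = rows.rename(columns={"above_baseline": "response",
                                "causative": "caus", "noncausative": "noncaus"})

    fits, weights = {}, {}
    for genre in corpora:
        for window in config.windows:
            sub = rows[(rows["window"] == window) & (rows["genre"] == genre)]
            seed = stage_seed(config.master_seed, "fit", "study2", genre, window)
            fit = bayes.fit_hierarchical(
                sub, predictor="layer",
                chains=config.chains, draws=config.draws, warmup=config.warmup,
                seed=seed, reference="raw", name=f"study2_{genre}_w{window}_layer",
            )
            null = bayes.fit_hierarchical(
                sub, predictor=None,
                chains=config.chains, draws=config.draws, warmup=config.warmup,
                seed=stage_seed(config.master_seed, "fitnull", "study2", genre,
                                window),
                name=f"study2_{genre}_w{window}_null",
            )
            fits[genre, window] = fit
            weights[genre, window] = bayes.compare_models(
                [fit, null], seed=stage_seed(config.master_seed, "bma", genre,
                                             window),
            )["weight"].to_dict()

    bundle = {"models": models, "distances": tables, "baselines": baselines,
              "rows": rows, "fits": fits, "weights": weights,
              "manifest": manifest}
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir), study=2)
    return bundle


def _write_bundle(bundle: dict, out_dir: Path, study: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["rows"].to_csv(out_dir / f"study{study}_rows.tsv", sep="\t",
                          index=False)
    summaries = {
        str(k): v.summary().reset_index().to_dict(orient="records")
        for k, v in bundle["fits"].items()
    }
    payload = {"summaries": summaries, "manifest": bundle["manifest"]}
    if "weights" in bundle:
        payload["weights"] = {str(k): v for k, v in bundle["weights"].items()}
    if "baselines" in bundle:
        payload["baselines"] = {
            str(k): b.mean_distance for k, b in bundle["baselines"].items()
        }
    with open(out_dir / f"study{study}_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
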