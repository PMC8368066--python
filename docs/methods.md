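# Methods

This note documents the models and procedures `seminfer` implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Data model and corpus handling

A corpus is a list of sessions, each an ordered list of utterances; a token
carries a lowercased lemma, a UPOS tag, a 1-based dependency head index
(0 = root) and a relation label.  Utterances must be single-rooted;
validation happens at construction, so every downstream consumer can assume
well-formedness.  The interchange format is CoNLL-U with `# newdoc id`
comments as session boundaries; only lemma/UPOS/head/deprel are stored, and
FORM repeats the lemma (the pipeline is defined over lemmatized text).

**Equal-token sampling.** To compare corpora of different sizes, whole
sessions are drawn uniformly at random without replacement until the next
session would overshoot the token budget; the overshooting session is kept
iff the total with it is strictly closer to the budget.  Sessions are never
split — sampling utterances across sessions would over-represent infrequent
vocabulary and break local semantic coherence.

## Training layers

- **raw** — the lemma sequence wrapped in `^^` … `$$`.  The markers give
  one-word utterances ("Run!") trainable structure (imperative-like frames)
  and are ordinary vocabulary items to the trainer.  They are rejected as
  lemmas at read time to prevent collision.
- **word class** — UPOS for every token, except verbs which keep their
  lemmas (verb semantics is the target of study); markers kept.
- **syntax** — one instance per *minimal dependency subtree* (a head plus
  its direct dependents, surface order).  Default encoding: verbs as
  lemmas, non-verb heads as UPOS, non-verb dependents as their relation
  labels.  The source figure for this layer is schematic, so the encoding
  is a documented choice; `LayerConfig(dependent_lemmas=True)` additionally
  interleaves dependents' lemmas.  No markers — subtrees are fragments, not
  utterances.
- **lexicon** — the same subtrees as plain lemmas (syntax expressed
  implicitly through lexical adjacency); no markers.

For layers other than raw, each utterance's raw instance and its layer
instances are shuffled together (seeded) and bundles are concatenated in
corpus order.  Shuffling *within* the utterance bundle — rather than
globally — keeps an utterance's semantics and syntax adjacent in the
stream while removing any systematic ordering between them.

## Embedding trainer

Skip-gram with negative sampling, written from first principles.  For a
pair with center input-vector **v**, context output-vector **u** and noise
vectors **u₁..u_k**:

    L = −log σ(u·v) − Σ_k log σ(−u_k·v)

- Pairs: all ordered (center, context) with |i−j| ≤ window inside one
  instance; order is dissolved (no positional features); window 1 spans
  exactly three tokens.
- Negatives: 5 per pair, drawn from unigram^0.75.  No frequent-word
  subsampling: in child-directed-like input the repetitive frames *are* the
  signal.
- Optimization: sequential per-pair SGD (the classic word2vec loop),
  learning rate decaying linearly 0.025 → 1e-4 over all updates, one epoch
  = one seeded shuffle of all pairs.  An earlier vectorized mini-batch
  variant was abandoned: summed scatter updates diverge when a small
  vocabulary puts many duplicates in a batch, and per-row averaging
  suppresses learning for frequent types.
- Determinism: randomness comes from an internal xorshift64* stream, so the
  numba-compiled kernel and its pure-python fallback execute the identical
  arithmetic; two runs with the same seed are bit-identical
  (single-threaded by construction).
- Headline settings are dimension 200, 100 epochs, windows 1–6; desk-scale
  runs (tests, acceptance, analysis defaults) use dim 48 and 25 epochs,
  which saturate on the small synthetic lexicons.
- The trainer's own frequency floor defaults to min_count 1; the ≥10 floor
  applies downstream when defining *frequent verbs* for baselines.
- Logits are clipped at ±30 before the sigmoid; the per-epoch mean loss is
  recorded and must stay finite, but no claim is attached to its value
  beyond a decreasing trend.

## Discrimination statistic

Cosine distance 1 − cos θ ∈ [0, 2] between every in-vocabulary causative
(23) and non-causative (9); full coverage gives 207 pairs.  Missing verbs
are dropped with a warning — real corpora do not guarantee coverage — and
coverage is visible in the table length.  The baseline is the mean distance
over random pairs of frequent verbs: unordered pairs of distinct verbs,
sampled uniformly with replacement across pairs (10000 by default), seeded.
Target verbs are *not* excluded from the baseline pool (configurable via
the verb set passed in).  Study 1 uses the cds raw model's baseline per
window; Study 2 uses each genre-and-window's own raw-model baseline, so
raw-layer rows are centered by construction and layer coefficients measure
deltas.

Neighbor joining (Saitou–Nei) over verb-by-verb distance matrices provides
the clustering view: ties on the Q criterion break to the lowest index
pair; negative branch lengths are retained and flagged, not clamped.
Output is Newick; agreement with scikit-bio's implementation is tested.

## Hierarchical models

Per window (Study 1) or per genre×window (Study 2):

    response ~ predictor + (1 + predictor | caus) + (1 + predictor | noncaus)

Gaussian likelihood; treatment coding with cds (genre) / raw (layer) as
reference.  Priors: Student-t(df 5, location 0, scale 10/2.5) on
intercept/coefficients; random-effect covariances get the Huang–Wand
(2013) prior — an inverse-Wishart/inverse-gamma mixture that induces
half-t(5, scale 2.5) marginals on the SDs and near-uniform correlations;
a diffuse inverse-gamma (1e-3, 1e-3) sits on the residual variance.

**Sampler.** Every full conditional is available in closed form (the t
priors via their normal scale-mixture), so inference is a blocked Gibbs
sampler rather than NUTS — no NUTS backend is assumed by the package.  Two
additions matter in practice:

- *Translation sweeps.*  The likelihood is flat along
  β_l → β_l + δ, {b_j[l] → b_j[l] − δ}; sampling δ from its conditional
  each iteration decorrelates the intercept (and slopes) from the
  random-effect means.  Without this the intercept's effective sample size
  collapses (observed ~20 at 1000 draws; ~500 with sweeps).
- *Defaults.*  4 chains × 2000 iterations (half warmup), seeded per chain;
  diagnostics (split-R̂, ESS via ArviZ) are part of every summary.  Tests
  run 2 × 800 where interval stability suffices.

Summaries report posterior means, HPD intervals at 0.80 and 0.90 (0.95 in
recovery tests), and `prob_above_zero` per fixed effect.  Model weights are
PSIS-LOO Pseudo-BMA+ (Bayesian bootstrap over pointwise elpd differences,
via ArviZ), with high Pareto-k observations surfaced as warnings.

**Measurement error.**  With a known baseline SD τ, the latent true
response is marginalized: y_obs ~ N(μ, σ² + τ²), and the *total* residual
variance is sampled from its conditional truncated to ≥ τ² (inverse-CDF
draw on the precision).  The reported σ is √(total − τ²).  A latent-y Gibbs
block was tried and rejected: it mixes pathologically when τ ≫ σ.  One
behavioral note: adding a known τ *below* the data's own residual noise
merely relabels variance and leaves fixed-effect intervals essentially
unchanged; intervals widen once τ dominates.  This is a property of the
model, not a bug, and the monotonicity test uses a low-noise fixture
accordingly.

## Probes

Per VERB token, the *verbal construction* is its context of up to w tokens
each side within the utterance.  Three statistics: (i) mean per-construction
share of nominal tokens (nominal = NOUN, PROPN, PRON — pronoun-heavy CDS
frames make pronouns nominals here; configurable); (ii) Shannon entropy
(bits) of nominal lemmas in verb contexts; (iii) Shannon entropy of
word-class frame signatures ("PRON verb NOUN").  Empty-context
constructions are excluded from (i) (undefined ratio) and counted as
signature "verb" in (iii).  Bootstrap: 1000 resampled units × 1000
iterations — constructions for (i) and (iii), nominal tokens for (ii) —
reporting the resample mean and SD.

## Synthetic data

The generator states a world with exactly the contrasts the analysis is
sensitive to, and nothing more:

- **cds_like** — MLU 4.0, 17% one-word utterances, a small frame inventory
  sampled peakily (concentration 0.6), pronoun/noun-dense verb contexts,
  and causatives placed in recurrent transitive agent-verb-patient frames
  with probability 0.9 (non-causatives likewise in their own distinct
  frames).
- **ads_like** — MLU 12.0, long varied frames with auxiliaries, adverbs and
  prepositional chains (a geometric PP-extension with rate 0.5 supplies
  length variance), a flatter frame distribution (concentration 2.5),
  larger lexicons, and frame biases of only 0.35.
- **null_contrast** — cds_like with both frame biases at 0: causatives and
  non-causatives draw from the identical frame distribution, so a correct
  pipeline should find nothing.

Utterances are frame templates carrying their own dependency structure
(verb roots, nsubj/dobj to nominals, det to nouns, and so on), filled from
per-class Zipfian lexicons (exponent 1.0, sizes tens-to-hundreds so
desk-scale training saturates).  Half of all verb slots are filled from the
32 target verbs (Zipf over the list), which guarantees ≥10 occurrences of
every target under the preset sizes.  MLU targets were calibrated once
against the presets' stated means (±0.5 tolerance is tested) and are not
revisited.

**What a green test establishes — and does not.**  The synthetic world
contains the *mechanism* under study (causatives sharing repetitive
transitive frames in CDS-like input) by construction.  End-to-end tests
therefore establish that the pipeline *detects a known injected contrast
and stays calibrated under a null* — they say nothing about whether real
child-directed speech has this structure, which requires the original
corpora.  The generator also omits: discourse structure, morphology,
homophony/polysemy, session heterogeneity within a genre, annotation noise
(parses are valid by construction), and the specific CLEAR relation
inventory.

## Numerical and procedural choices

- Stage seeds are SHA-256 hashes of (master seed, stage coordinates),
  truncated below 2³¹ — no accidental seed sharing between stages.
- Cosine distances are clipped to [0, 2] against float rounding only.
- NJ tie-break: lowest (i, j); 3-taxon base case solved in closed form.
- HPD intervals use the shortest-interval-of-sorted-draws estimator.
- The verbless and PP-extension rates, frame inventories and biases are
  fixed properties of the presets; experiments vary seeds, sizes, windows,
  dims and epochs only.

## Known limitations

- Desk-scale corpora (10⁴–10⁵ tokens) are three orders of magnitude below
  the ~3.2M-token corpora the design targets; absolute effect sizes here
  are not comparable to corpus-scale ones, only directions and calibration.
- The Gibbs sampler assumes the Gaussian likelihood; it would need
  rethinking for non-Gaussian responses (out of scope).
- Study 2 on the synthetic presets shows annotation layers *helping* in
  both genres: the generator injects no genre-specific syntax contrast, so
  the layer effect's genre dependence (the interesting corpus-scale
  finding) is not part of the stated synthetic world.
- PSIS-LOO on crossed random-effect models can flag high Pareto-k for
  influential verbs at small n; weights should be read alongside those
  warnings.
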