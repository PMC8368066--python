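import warnings
from io import StringIO

import numpy as np
import pytest

from seminfer.discrimination import (
    CAUSATIVES,
    NONCAUSATIVES,
    BaselineEstimate,
    VerbSets,
    above_baseline,
    cosine_distance,
    estimate_baseline,
    frequent_verbs,
    neighbor_joining,
    pairwise_distances,
    verb_distance_matrix,
)
from seminfer.sgns import EmbeddingModel, Vocab


def make_model(words, vectors, window=1):
    vocab = Vocab(id_of={w: i for i, w in enumerate(words)},
                  count_of={w: 10 for w in words}, min_count=1)
    vectors = np.asarray(vectors, dtype=float)
    return EmbeddingModel(vocab=vocab, vectors=vectors,
                          out_vectors=np.zeros_like(vectors), window=window,
                          dim=vectors.shape[1], epochs=1, seed=0,
                          loss_trace=[0.0])


@pytest.fixture
def full_coverage_model(rng):
    words = list(CAUSATIVES) + list(NONCAUSATIVES)
    return make_model(words, rng.normal(size=(len(words), 12)))


class TestCosineDistance:
    def test_identical_vectors_give_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_vectors_give_two(self):
        v = np.array([1.0, -2.0, 0.5])
        assert cosine_distance(v, -v) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_vectors_give_one(self):
        assert cosine_distance(np.array([1.0, 0.0]),
                               np.array([0.0, 3.0])) == pytest.approx(1.0)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(100):
            u, v = rng.normal(size=(2, 6))
            d = cosine_distance(u, v)
            assert d == pytest.approx(cosine_distance(v, u))
            assert 0.0 <= d <= 2.0

    def test_zero_iff_positive_scalar_multiple(self, rng):
        v = rng.normal(size=5)
        assert cosine_distance(v, 2.5 * v) == pytest.approx(0.0, abs=1e-12)
        assert cosine_distance(v, -0.1 * v) == pytest.approx(2.0, abs=1e-12)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(3), np.ones(3))


class TestPairwiseDistances:
    def test_full_coverage_gives_207_entries(self, full_coverage_model):
        table = pairwise_distances(full_coverage_model)
        assert len(table) == 23 * 9 == 207

    def test_missing_causative_drops_nine_pairs_with_warning(self, rng):
        words = list(CAUSATIVES[1:]) + list(NONCAUSATIVES)
        model = make_model(words, rng.normal(size=(len(words), 8)))
        with pytest.warns(UserWarning, match="begin"):
            table = pairwise_distances(model)
        assert len(table) == 22 * 9 == 198

    def test_entries_match_per_pair_recomputation(self, full_coverage_model):
        from seminfer.sgns import vector

        table = pairwise_distances(full_coverage_model)
        for row in table.sample(20, random_state=0).itertuples():
            expected = cosine_distance(
                vector(full_coverage_model, row.causative),
                vector(full_coverage_model, row.noncausative))
            assert row.distance == pytest.approx(expected)


class TestFrequentVerbs:
    def test_floor_boundary(self, tiny_corpus):
        # "open" occurs twice as VERB, "run" once
        assert frequent_verbs(tiny_corpus, floor=2) == {"open"}
        assert frequent_verbs(tiny_corpus, floor=1) == {"open", "run"}
        assert frequent_verbs(tiny_corpus, floor=3) == set()

    def test_counts_equal_brute_force_recount(self, cds_corpus):
        counts = {}
        for u in cds_corpus:
            for t in u.tokens:
                if t.upos == "VERB":
                    counts[t.lemma] = counts.get(t.lemma, 0) + 1
        expected = {w for w, c in counts.items() if c >= 10}
        assert frequent_verbs(cds_corpus, 10) == expected


class TestBaseline:
    def test_identical_vectors_give_zero_baseline(self):
        model = make_model(["u", "v", "w"], np.ones((3, 4)))
        est = estimate_baseline(model, {"u", "v", "w"}, n_pairs=100, seed=1)
        assert est.mean_distance == pytest.approx(0.0, abs=1e-12)

    def test_two_verbs_give_their_exact_distance(self, rng):
        vecs = rng.normal(size=(2, 6))
        model = make_model(["u", "v"], vecs)
        est = estimate_baseline(model, {"u", "v"}, n_pairs=500, seed=2)
        assert est.mean_distance == pytest.approx(
            cosine_distance(vecs[0], vecs[1]))

    def test_large_sample_approaches_exhaustive_mean(self, rng):
        words = list("abcde")
        vecs = rng.normal(size=(5, 8))
        model = make_model(words, vecs)
        exhaustive = np.mean([
            cosine_distance(vecs[i], vecs[j])
            for i in range(5) for j in range(i + 1, 5)])
        est = estimate_baseline(model, set(words), n_pairs=40000, seed=3)
        # Monte-Carlo error: sd of pair distances / sqrt(n), generous x5
        assert est.mean_distance == pytest.approx(exhaustive, abs=0.02)

    def test_seed_determinism(self, full_coverage_model):
        verbs = set(CAUSATIVES[:6])
        a = estimate_baseline(full_coverage_model, verbs, n_pairs=200, seed=7)
        b = estimate_baseline(full_coverage_model, verbs, n_pairs=200, seed=7)
        assert a.mean_distance == b.mean_distance

    def test_fewer_than_two_verbs_errors(self, full_coverage_model):
        with pytest.raises(ValueError):
            estimate_baseline(full_coverage_model, {"open"}, n_pairs=10, seed=0)


class TestAboveBaseline:
    def test_distance_equal_to_baseline_scores_zero(self, full_coverage_model):
        table = pairwise_distances(full_coverage_model)
        base = BaselineEstimate(mean_distance=float(table["distance"].iloc[0]),
                                window=1)
        scored = above_baseline(table, base)
        assert scored["above_baseline"].iloc[0] == pytest.approx(0.0)

    def test_207_scores_and_linearity(self, full_coverage_model):
        table = pairwise_distances(full_coverage_model)
        base = BaselineEstimate(mean_distance=0.9, window=1)
        scored = above_baseline(table, base)
        assert len(scored) == 207
        assert scored["above_baseline"].mean() == pytest.approx(
            table["distance"].mean() - 0.9)

    def test_window_mismatch_errors(self, full_coverage_model):
        table = pairwise_distances(full_coverage_model)  # window 1
        base = BaselineEstimate(mean_distance=0.9, window=3)
        with pytest.raises(ValueError, match="window"):
            above_baseline(table, base)


def _newick_path_distances(newick: str):
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    return tree.tip_tip_distances()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        nwk = neighbor_joining(D, ["a", "b", "c"])
        # 3-point equations: la = (dab + dac - dbc)/2 = 1, lb = 2, lc = 3
        assert nwk == "(a:1,b:2,c:3);"

    def test_additive_four_taxon_tree_recovered_exactly(self):
        # tree: ((a:1,b:2):1.5,(c:1,d:3)); path distances are additive
        D = np.array([
            [0.0, 3.0, 3.5, 5.5],
            [3.0, 0.0, 4.5, 6.5],
            [3.5, 4.5, 0.0, 4.0],
            [5.5, 6.5, 4.0, 0.0],
        ])
        nwk = neighbor_joining(D, ["a", "b", "c", "d"])
        dm = _newick_path_distances(nwk)
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                assert dm[x, y] == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_reference_implementation_on_random_matrices(self, rng):
        from skbio import DistanceMatrix, TreeNode
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            pts = rng.random((6, 3))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            ids = [f"x{i}" for i in range(6)]
            mine = TreeNode.read(StringIO(neighbor_joining(D, ids)))
            ref = skbio_nj(DistanceMatrix(D, ids=ids))
            assert mine.compare_rfd(ref) == 0.0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(D)

    def test_verb_distance_matrix_is_valid_nj_input(self, full_coverage_model):
        D, present = verb_distance_matrix(
            full_coverage_model, list(CAUSATIVES[:4]) + ["go", "say"])
        assert D.shape == (6, 6)
        nwk = neighbor_joining(D, present)
        assert nwk.endswith(";")
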