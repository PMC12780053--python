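"""Pair features, negative sampling, classifier backends, candidate ranking."""

import numpy as np
import pytest
from sklearn.model_selection import cross_val_score

import fgcnmf as f
from fgcnmf.mf import EmbeddingMatrix
from fgcnmf.pair_model import (
    CLASSIFIERS,
    ClassifierSpec,
    pair_features,
    rank_candidates,
    sample_negatives,
    train,
)


def toy_embedding(n_m, n_d, d, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"m{i}" for i in range(n_m)] + [f"d{i}" for i in range(n_d)]
    return EmbeddingMatrix(ids, rng.normal(size=(n_m + n_d, d)))


class TestPairFeatures:
    def test_concat_order(self):
        F = toy_embedding(3, 2, 2, seed=1)
        out = pair_features(F, [(0, 0)], n_m=3, pair_op="concat")
        expected = np.concatenate([F.vectors[0], F.vectors[3]])
        assert np.array_equal(out[0], expected)

    def test_shapes(self):
        F = toy_embedding(4, 3, 5)
        pairs = [(0, 0), (1, 2), (3, 1)]
        assert pair_features(F, pairs, 4, "concat").shape == (3, 10)
        assert pair_features(F, pairs, 4, "hadamard").shape == (3, 5)
        assert pair_features(F, pairs, 4, "mean").shape == (3, 5)

    def test_concat_round_trip_recovers_rows(self):
        F = toy_embedding(4, 3, 6, seed=2)
        pairs = [(2, 1), (0, 2)]
        out = pair_features(F, pairs, 4, "concat")
        for row, (m, d) in zip(out, pairs):
            assert np.array_equal(row[:6], F.vectors[m])
            assert np.array_equal(row[6:], F.vectors[4 + d])

    def test_elementwise_ops_match_definitions(self):
        F = toy_embedding(2, 2, 3, seed=3)
        had = pair_features(F, [(1, 0)], 2, "hadamard")[0]
        mean = pair_features(F, [(1, 0)], 2, "mean")[0]
        assert np.allclose(had, F.vectors[1] * F.vectors[2])
        assert np.allclose(mean, (F.vectors[1] + F.vectors[2]) / 2)

    def test_rejects_out_of_range(self):
        F = toy_embedding(3, 2, 2)
        with pytest.raises(IndexError):
            pair_features(F, [(3, 0)], 3)
        with pytest.raises(IndexError):
            pair_features(F, [(0, 2)], 3)


class TestSampleNegatives:
    def _md(self):
        values = np.zeros((5, 5), dtype=int)
        values[0, 0] = values[1, 2] = values[4, 4] = 1
        return f.AssociationMatrix(
            [f"m{i}" for i in range(5)], [f"d{i}" for i in range(5)], values
        )

    def test_one_to_one_count_and_exclusions(self):
        MD = self._md()
        n_pos = MD.n_links
        neg = sample_negatives(MD, n_pos, seed=0)
        assert len(neg) == n_pos
        assert all(MD.values[i, j] == 0 for i, j in neg)
        exclude = set(neg)
        more = sample_negatives(MD, 5, seed=1, exclude=exclude)
        assert not set(more) & exclude
        assert all(MD.values[i, j] == 0 for i, j in more)

    def test_seeded_determinism(self):
        MD = self._md()
        assert sample_negatives(MD, 6, seed=7) == sample_negatives(MD, 6, seed=7)

    def test_inclusion_frequencies_uniform(self):
        MD = self._md()
        n_zero = int((MD.values == 0).sum())
        counts = {}
        n_draws, k = 2000, 4
        for s in range(n_draws):
            for pair in sample_negatives(MD, k, seed=s):
                counts[pair] = counts.get(pair, 0) + 1
        p = k / n_zero
        tol = 4 * np.sqrt(n_draws * p * (1 - p))
        for pair, c in counts.items():
            assert abs(c - n_draws * p) < tol, (pair, c)

    def test_rejects_oversampling(self):
        MD = self._md()
        with pytest.raises(ValueError, match="22"):
            sample_negatives(MD, 23, seed=0)


class TestTrain:
    def _separable(self, d=4, n=40, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.ones((n, d)) + 0.05 * rng.normal(size=(n, d))
        neg = -np.ones((n, d)) + 0.05 * rng.normal(size=(n, d))
        X = np.vstack([pos, neg])
        y = np.r_[np.ones(n, int), np.zeros(n, int)]
        return X, y

    def test_separable_data_fit_perfectly(self):
        X, y = self._separable()
        model = train(X, y, ClassifierSpec("extra_trees", seed=0))
        scores = model.predict_scores(X)
        assert np.all((scores > 0.5) == (y == 1))

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 8))
        y = rng.permutation(np.r_[np.ones(250, int), np.zeros(250, int)])
        from sklearn.ensemble import ExtraTreesClassifier

        aucs = cross_val_score(
            ExtraTreesClassifier(100, random_state=0), X, y, cv=5, scoring="roc_auc"
        )
        assert 0.4 <= aucs.mean() <= 0.6

    def test_same_seed_same_scores(self):
        X, y = self._separable(seed=5)
        a = train(X, y, ClassifierSpec("extra_trees", seed=9)).predict_scores(X)
        b = train(X, y, ClassifierSpec("extra_trees", seed=9)).predict_scores(X)
        assert np.array_equal(a, b)

    def test_row_order_invariance_for_trees(self):
        X, y = self._separable(seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        a = train(X, y, ClassifierSpec("extra_trees", seed=1)).predict_scores(X)
        b = train(X[perm], y[perm], ClassifierSpec("extra_trees", seed=1)).predict_scores(X)
        assert np.allclose(a, b)

    @pytest.mark.parametrize("algo", CLASSIFIERS)
    def test_all_backends_score_in_unit_interval(self, algo):
        X, y = self._separable(n=30)
        model = train(X, y, ClassifierSpec(algo, seed=0))
        scores = model.predict_scores(X)
        assert scores.shape == (60,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_rejects_degenerate_input(self):
        X, y = self._separable()
        with pytest.raises(ValueError, match="single class"):
            train(X, np.ones(len(y), int), ClassifierSpec("extra_trees"))
        with pytest.raises(ValueError, match="10"):
            train(X[:5], y[:5], ClassifierSpec("extra_trees"))
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("perceptron")


class TestRankCandidates:
    def _setup(self):
        # embedding engineered so hadamard(pos) = +1s, hadamard(neg) = -1s
        n_m, n_d, d = 6, 2, 3
        vec = np.ones((n_m + n_d, d))
        vec[:n_m] = -1.0
        vec[2] = 1.0  # microbe 2 aligns with the diseases
        ids = [f"m{i}" for i in range(n_m)] + [f"d{i}" for i in range(n_d)]
        F = EmbeddingMatrix(ids, vec)
        rng = np.random.default_rng(0)
        pos = np.ones((30, d)) + 0.05 * rng.normal(size=(30, d))
        neg = -np.ones((30, d)) + 0.05 * rng.normal(size=(30, d))
        X = np.vstack([pos, neg])
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        model = train(X, y, ClassifierSpec("extra_trees", seed=0))
        values = np.zeros((n_m, n_d), dtype=int)
        MD = f.AssociationMatrix(ids[:n_m], ids[n_m:], values)
        return model, F, MD

    def test_planted_microbe_ranks_first(self):
        model, F, MD = self._setup()
        ranked = rank_candidates(model, F, 0, MD, top_k=3, pair_op="hadamard")
        assert ranked[0][0] == "m2"
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_known_pairs_filtered(self):
        model, F, MD = self._setup()
        MD.values[2, 0] = 1  # the planted winner is already known
        ranked = rank_candidates(model, F, 0, MD, top_k=10, pair_op="hadamard")
        assert all(mid != "m2" for mid, _ in ranked)

    def test_all_known_returns_empty(self):
        model, F, MD = self._setup()
        MD.values[:, 0] = 1
        assert rank_candidates(model, F, 0, MD, top_k=5, pair_op="hadamard") == []

    def test_top_k_caps_and_warns(self):
        model, F, MD = self._setup()
        with pytest.warns(UserWarning, match="candidates"):
            ranked = rank_candidates(model, F, 0, MD, top_k=50, pair_op="hadamard")
        assert len(ranked) == MD.n_microbes

    def test_top_20_protocol_length(self):
        model, F, MD = self._setup()
        ranked = rank_candidates(model, F, 1, MD, top_k=20, pair_op="hadamard")
        assert len(ranked) <= 20
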