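"""Metric suite: aggregation rule, confusion counting, Eq.-style metrics,
embeddings and t-SNE output contracts."""

import warnings

import numpy as np
import pytest

from sincvoice.evaluation import (
    ConfusionMatrix,
    aggregate_utterance,
    collect_embeddings,
    confusion,
    metrics,
    tsne_scatter,
)


class TestAggregateUtterance:
    def test_single_chunk_returns_its_argmax(self):
        idx, post = aggregate_utterance([[0.2, 0.7, 0.1]])
        assert idx == 1
        assert np.allclose(post, [0.2, 0.7, 0.1])

    def test_tie_breaks_to_lowest_class_index(self):
        idx, post = aggregate_utterance([[0.9, 0.1], [0.1, 0.9]])
        assert np.allclose(post, [0.5, 0.5])
        assert idx == 0

    def test_mean_of_posteriors_sums_to_one(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=10)
        _, post = aggregate_utterance(probs)
        assert post.sum() == pytest.approx(1.0)

    def test_empty_chunk_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_utterance(np.empty((0, 3)))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["a", "b", "c"] * 4
        cm = confusion(labels, labels, ["a", "b", "c"])
        assert np.array_equal(cm.counts, 4 * np.eye(3, dtype=int))

    def test_hand_counted_binary_example(self):
        cm = confusion(["a", "a", "b", "b"], ["a", "b", "b", "b"], ["a", "b"])
        assert np.array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_row_percentages_sum_to_100(self):
        cm = confusion(["a", "a", "b", "b"], ["a", "b", "b", "b"], ["a", "b"])
        assert np.allclose(cm.row_percent().sum(axis=1), 100.0)

    def test_percentages_consistent_with_counts(self):
        rng = np.random.default_rng(1)
        true = rng.choice(list("abc"), size=60)
        pred = rng.choice(list("abc"), size=60)
        cm = confusion(true, pred, ["a", "b", "c"])
        pct = cm.row_percent()
        sums = cm.counts.sum(axis=1)
        for i in range(3):
            assert np.allclose(pct[i], 100.0 * cm.counts[i] / sums[i])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a"], ["z"], ["a", "b"])


def _brute_force_metrics(true, pred, class_order):
    """Independent oracle: count TP/TN/FP/FN per class from definitions."""
    n = len(true)
    correct = sum(t == p for t, p in zip(true, pred))
    sens = {}
    for cls in class_order:
        tp = sum(1 for t, p in zip(true, pred) if t == cls and p == cls)
        fn = sum(1 for t, p in zip(true, pred) if t == cls and p != cls)
        if tp + fn > 0:
            sens[cls] = 100.0 * tp / (tp + fn)
    return (100.0 * correct / n, sens,
            float(np.mean(list(sens.values()))))


class TestMetrics:
    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(10 * np.eye(3, dtype=int), ["a", "b", "c"])
        rep = metrics(cm)
        assert rep.accuracy == 100.0
        assert rep.uar == 100.0

    def test_hand_counted_binary_detection(self):
        # rows fixed order [negative, positive]
        cm = ConfusionMatrix(np.array([[7, 3], [2, 8]]), ["neg", "pos"])
        rep = metrics(cm, positive_label="pos")
        assert rep.accuracy == pytest.approx(75.0)
        assert rep.sensitivity_per_class["pos"] == pytest.approx(80.0)
        assert rep.specificity == pytest.approx(70.0)

    def test_uar_is_arithmetic_mean_of_sensitivities(self):
        counts = np.array([[6, 2, 2], [1, 7, 2], [1, 1, 8]])
        cm = ConfusionMatrix(counts, ["x", "y", "z"])
        rep = metrics(cm)
        assert rep.uar == pytest.approx((60.0 + 70.0 + 80.0) / 3)

    def test_agrees_with_brute_force_on_random_label_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(k, 200))
            class_order = [f"c{i}" for i in range(k)]
            true = [class_order[i] for i in rng.integers(0, k, size=n)]
            pred = [class_order[i] for i in rng.integers(0, k, size=n)]
            cm = confusion(true, pred, class_order)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = metrics(cm)
            acc, sens, uar = _brute_force_metrics(true, pred, class_order)
            assert abs(rep.accuracy - acc) < 1e-9
            assert abs(rep.uar - uar) < 1e-9
            for cls, val in sens.items():
                assert abs(rep.sensitivity_per_class[cls] - val) < 1e-9

    def test_uar_equals_accuracy_on_balanced_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 30, size=(k, k))
            row = counts.sum(axis=1).max()
            for i in range(k):  # pad the diagonal to equalize row sums
                counts[i, i] += row - counts[i].sum()
            cm = ConfusionMatrix(counts, [f"c{i}" for i in range(k)])
            rep = metrics(cm)
            assert rep.uar == pytest.approx(rep.accuracy, abs=1e-9)

    def test_zero_row_excluded_from_uar_with_warning(self):
        counts = np.array([[5, 0, 0], [0, 0, 0], [0, 0, 5]])
        cm = ConfusionMatrix(counts, ["a", "b", "c"])
        with pytest.warns(UserWarning):
            rep = metrics(cm)
        assert "b" not in rep.sensitivity_per_class
        assert rep.uar == pytest.approx(100.0)

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"])
        with pytest.raises(ValueError):
            metrics(cm)


class TestEmbeddingsAndTsne:
    @pytest.fixture(scope="class")
    def embedding_table(self, small_trained_pair):
        from sincvoice.vowelsynth import SynthParams, synth_vowel

        sinc, _cnn = small_trained_pair
        params = SynthParams(duration_s=0.5)
        utts = [synth_vowel(lbl, params=params, seed=100 + i)
                for i, lbl in enumerate(["Neo", "Neo", "Neo", "Neo", "Neo",
                                         "VP", "VP", "VP", "VP", "VP"])]
        return collect_embeddings(sinc, utts)

    def test_one_row_per_utterance_with_model_width(self, embedding_table,
                                                    small_trained_pair):
        sinc, _ = small_trained_pair
        feat_cols = [c for c in embedding_table.columns if c.startswith("e")]
        assert len(embedding_table) == 10
        assert len(feat_cols) == sinc.embed_dim

    def test_identical_utterances_get_identical_embeddings(self,
                                                           small_trained_pair):
        from sincvoice.vowelsynth import SynthParams, synth_vowel

        sinc, _ = small_trained_pair
        w = synth_vowel("Neo", params=SynthParams(duration_s=0.5), seed=0)
        df = collect_embeddings(sinc, [w, w])
        feat_cols = [c for c in df.columns if c.startswith("e")]
        assert np.array_equal(df.loc[0, feat_cols].to_numpy(),
                              df.loc[1, feat_cols].to_numpy())

    def test_tsne_point_count_and_determinism(self, embedding_table, tmp_path):
        out = tmp_path / "tsne.png"
        a = tsne_scatter(embedding_table, seed=3, out_png=out)
        b = tsne_scatter(embedding_table, seed=3)
        assert a.shape == (10, 2)
        assert np.array_equal(a, b)
        assert out.exists()

    def test_tsne_separates_distinct_classes(self, embedding_table):
        coords = tsne_scatter(embedding_table, seed=3)
        labels = embedding_table["label"].to_numpy()
        inter, intra = [], []
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                d = np.linalg.norm(coords[i] - coords[j])
                (intra if labels[i] == labels[j] else inter).append(d)
        assert np.mean(inter) > np.mean(intra)

    def test_too_few_points_rejected(self, embedding_table):
        with pytest.raises(ValueError):
            tsne_scatter(embedding_table.iloc[:2], seed=0)
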