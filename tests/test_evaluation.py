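import numpy as np
import pytest

from ddiwalk import evaluation as ev
from ddiwalk.errors import ValidationError
from ddiwalk.io_formats import DDIPair, PredictionResult


def preds(labels_conf):
    return [
        PredictionResult(f"a{i}", f"b{i}", lab, conf)
        for i, (lab, conf) in enumerate(labels_conf)
    ]


def make_pairs(counts: dict[int, int]):
    pairs = []
    for t, n in counts.items():
        for i in range(n):
            pairs.append(DDIPair(f"t{t}x{i}", f"t{t}y{i}", t))
    return pairs


class TestStratifiedSplit:
    def test_single_type_seven_three(self):
        train, test = ev.stratified_split(make_pairs({1: 10}), 0.7, seed=0)
        assert (len(train), len(test)) == (7, 3)

    def test_deterministic_given_seed(self):
        pairs = make_pairs({1: 10, 2: 20, 3: 7})
        s1 = ev.stratified_split(pairs, 0.7, seed=5)
        s2 = ev.stratified_split(pairs, 0.7, seed=5)
        assert s1 == s2

    def test_per_type_counts_within_one_pair(self):
        counts = {1: 10, 2: 23, 3: 4, 4: 51}
        train, _ = ev.stratified_split(make_pairs(counts), 0.7, seed=1)
        for t, n in counts.items():
            n_train = sum(p.ddi_type == t for p in train)
            assert abs(n_train - 0.7 * n) <= 1.0

    def test_disjoint_and_exhaustive(self):
        pairs = make_pairs({1: 9, 2: 6})
        train, test = ev.stratified_split(pairs, 0.7, seed=2)
        assert sorted(train + test, key=str) == sorted(pairs, key=str)
        assert not set(map(str, train)) & set(map(str, test))

    def test_singleton_type_goes_to_train(self):
        train, test = ev.stratified_split(make_pairs({1: 1, 2: 10}), 0.7, seed=0)
        assert sum(p.ddi_type == 1 for p in train) == 1
        assert all(p.ddi_type != 1 for p in test)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            ev.stratified_split([], 0.7, seed=0)


class TestStratifiedFolds:
    def test_sixteen_per_type_gives_folds_of_four(self):
        pairs = make_pairs({1: 16, 2: 16})
        folds = ev.stratified_folds(pairs, k=4, seed=0)
        for fold in folds:
            for t in (1, 2):
                assert sum(pairs[i].ddi_type == t for i in fold) == 4

    def test_partition_property(self):
        pairs = make_pairs({1: 10, 2: 13, 3: 8})
        folds = ev.stratified_folds(pairs, k=4, seed=3)
        flat = sorted(i for fold in folds for i in fold)
        assert flat == list(range(len(pairs)))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            ev.stratified_folds(make_pairs({1: 4}), k=1)


class TestComputeMetrics:
    def test_hand_worked_confusion(self):
        """truth [1,1,2] vs pred [1,2,2]: acc 2/3, macro P = macro R = F1 = 0.75."""
        report = ev.compute_metrics(
            [1, 1, 2], preds([(1, 0.9), (2, 0.8), (2, 0.7)]), n_types=2
        )
        assert report.accuracy == pytest.approx(2 / 3)
        assert report.macro_precision == pytest.approx(0.75)
        assert report.macro_recall == pytest.approx(0.75)
        assert report.macro_f1 == pytest.approx(0.75)

    def test_perfect_predictions(self):
        report = ev.compute_metrics(
            [1, 2, 3], preds([(1, 1.0), (2, 1.0), (3, 1.0)]), n_types=3
        )
        assert (
            report.accuracy
            == report.macro_precision
            == report.macro_recall
            == report.macro_f1
            == 1.0
        )
        assert report.per_type_accuracy == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_all_abstentions(self):
        report = ev.compute_metrics(
            [1, 2], preds([(None, 0.2), (None, 0.3)]), n_types=2
        )
        assert report.accuracy == 0.0 and report.abstention_rate == 1.0

    def test_abstention_excluded_from_precision_denominator(self):
        # one correct type-1 call, one abstention on a type-1 pair
        report = ev.compute_metrics(
            [1, 1], preds([(1, 0.9), (None, 0.1)]), n_types=1
        )
        assert report.macro_precision == 1.0  # 1 TP / 1 prediction
        assert report.macro_recall == 0.5     # abstention is a recall failure

    def test_accuracy_consistent_with_frequency_weighted_per_type(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 5, size=200).tolist()
        predicted = [
            (int(t) if rng.random() < 0.6 else int(rng.integers(1, 5)), 0.9)
            for t in truth
        ]
        report = ev.compute_metrics(truth, preds(predicted), n_types=4)
        weighted = sum(
            report.per_type_accuracy[t] * truth.count(t) for t in set(truth)
        ) / len(truth)
        assert report.accuracy == pytest.approx(weighted)

    def test_brute_force_oracle_random_vectors(self):
        """Confusion-matrix arithmetic recomputed from scratch on random data."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(3, 50))
            n_types = int(rng.integers(2, 6))
            truth = rng.integers(1, n_types + 1, size=n).tolist()
            predicted = [
                None if rng.random() < 0.15 else int(rng.integers(1, n_types + 1))
                for _ in range(n)
            ]
            report = ev.compute_metrics(
                truth, preds([(p, 0.5) for p in predicted]), n_types
            )
            acc = sum(p == t for p, t in zip(predicted, truth)) / n
            precs, recs = [], []
            for t in sorted(set(truth)):
                tp = sum(p == t and y == t for p, y in zip(predicted, truth))
                np_t = sum(p == t for p in predicted)
                precs.append(tp / np_t if np_t else 0.0)
                recs.append(tp / truth.count(t))
            assert report.accuracy == pytest.approx(acc)
            assert report.macro_precision == pytest.approx(np.mean(precs))
            assert report.macro_recall == pytest.approx(np.mean(recs))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ev.compute_metrics([1], preds([(1, 0.5), (2, 0.5)]), 2)


class TestRankFalsePositives:
    def test_sorted_by_descending_confidence(self):
        truth = [1, 1, 1, 1]
        predictions = preds([(2, 0.9), (1, 0.99), (2, 0.5), (2, 0.7)])
        top = ev.rank_false_positives(truth, predictions, top_k=2)
        assert [e[3] for e in top] == [0.9, 0.7]

    def test_no_errors_empty(self):
        assert ev.rank_false_positives([1], preds([(1, 0.9)]), 10) == []

    def test_abstentions_are_not_false_positives(self):
        top = ev.rank_false_positives([1], preds([(None, 0.9)]), 10)
        assert top == []

    def test_confidence_ties_break_lexicographically(self):
        predictions = [
            PredictionResult("z", "z2", 2, 0.8),
            PredictionResult("a", "a2", 2, 0.8),
        ]
        top = ev.rank_false_positives([1, 1], predictions, 10)
        assert [e[0][0] for e in top] == ["a", "z"]


class TestCrossValidate:
    def _setup(self):
        from test_feature_model import separable_setup

        return separable_setup(n_drugs=18, seed=7)

    def test_reports_and_summary(self):
        from ddiwalk.feature_model import ModelConfig

        red, pairs = self._setup()
        cfg = ModelConfig(hidden_layers=1, hidden_nodes=32, epochs=10, n_types=3, seed=0)
        reports, summary = ev.cross_validate(pairs, red, cfg, k=4, seed=0)
        assert len(reports) == 4
        accs = [r.accuracy for r in reports]
        assert min(accs) <= summary["mean_accuracy"] <= max(accs)

    def test_invariant_to_input_ordering(self):
        from ddiwalk.feature_model import ModelConfig

        red, pairs = self._setup()
        cfg = ModelConfig(hidden_layers=1, hidden_nodes=16, epochs=5, n_types=3, seed=1)
        r1, s1 = ev.cross_validate(pairs, red, cfg, k=3, seed=4)
        r2, s2 = ev.cross_validate(list(reversed(pairs)), red, cfg, k=3, seed=4)
        assert s1 == s2
        assert [r.accuracy for r in r1] == [r.accuracy for r in r2]
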