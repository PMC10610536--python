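import numpy as np
import pytest

from ddiwalk import feature_model as fm
from ddiwalk.errors import ValidationError
from ddiwalk.io_formats import DDIPair, ProfileMatrix


def make_profiles(n_drugs=8, n_feat=8, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"d{i}" for i in range(n_drugs)]
    cols = [f"c{j}" for j in range(n_feat)]
    ssp = ProfileMatrix(ids, cols, rng.random((n_drugs, n_feat)))
    psp = ProfileMatrix(ids, cols, rng.random((n_drugs, n_feat)))
    return ssp, psp


class TestFitReduce:
    def test_low_rank_exact_reconstruction(self):
        rng = np.random.default_rng(1)
        ids = [f"d{i}" for i in range(10)]
        base = rng.random((10, 2)) @ rng.random((2, 10))  # rank-2
        prof = ProfileMatrix(ids, list(ids), base)
        red = fm.fit_reduce(prof, prof, d_ssp=2, d_psp=2)
        recon = red.ssp_components @ red.ssp_basis + red.ssp_mean
        assert np.linalg.norm(recon - base) <= 1e-8

    def test_full_basis_retains_all_variance(self):
        ssp, psp = make_profiles(7, 6)
        red = fm.fit_reduce(ssp, psp, d_ssp=6, d_psp=6)
        centered = ssp.values - ssp.values.mean(axis=0)
        assert np.sum(red.ssp_components**2) == pytest.approx(np.sum(centered**2))

    def test_duplicated_rows_reduce_identically(self):
        ids = ["a", "b", "c", "d"]
        vals = np.array([[1.0, 2, 3], [1.0, 2, 3], [4, 5, 6], [0, 1, 0]])
        prof = ProfileMatrix(ids, ["x", "y", "z"], vals)
        red = fm.fit_reduce(prof, prof, d_ssp=2, d_psp=2)
        assert np.allclose(red.ssp_components[0], red.ssp_components[1])

    def test_over_rank_request_warns_and_truncates(self):
        ids = ["a", "b", "c"]
        vals = np.outer([1.0, 2, 3], [1.0, 0, 1])  # rank 1
        prof = ProfileMatrix(ids, ["x", "y", "z"], vals)
        with pytest.warns(UserWarning, match="rank"):
            red = fm.fit_reduce(prof, prof, d_ssp=3, d_psp=3)
        assert red.d_ssp < 3

    def test_repeat_fit_deterministic(self):
        ssp, psp = make_profiles(12, 10)
        r1 = fm.fit_reduce(ssp, psp, 5, 5)
        r2 = fm.fit_reduce(ssp, psp, 5, 5)
        assert np.array_equal(r1.ssp_components, r2.ssp_components)
        assert np.array_equal(r1.psp_basis, r2.psp_basis)


class TestPairFeatures:
    def test_length_is_twice_component_sum(self):
        ssp, psp = make_profiles(10, 10)
        red = fm.fit_reduce(ssp, psp, d_ssp=4, d_psp=6)
        vec = fm.pair_features(("d0", "d1"), red)
        assert vec.shape == (2 * (4 + 6),)

    def test_blocks_stack_in_order_and_swap(self):
        ssp, psp = make_profiles(6, 6)
        red = fm.fit_reduce(ssp, psp, d_ssp=2, d_psp=3)
        ab = fm.pair_features(("d0", "d1"), red)
        s0, p0 = red.row("d0")
        s1, p1 = red.row("d1")
        assert np.array_equal(ab, np.concatenate([s0, p0, s1, p1]))
        ba = fm.pair_features(("d1", "d0"), red)
        assert np.array_equal(ba, np.concatenate([s1, p1, s0, p0]))
        assert not np.array_equal(ab, ba)

    def test_unknown_drug_rejected(self):
        ssp, psp = make_profiles(4, 4)
        red = fm.fit_reduce(ssp, psp, 2, 2)
        with pytest.raises(ValidationError, match="ghost"):
            fm.pair_features(("d0", "ghost"), red)


def separable_setup(n_drugs=24, seed=5):
    """Three well-separated drug clusters; label = cluster of drug A."""
    rng = np.random.default_rng(seed)
    ids = [f"d{i}" for i in range(n_drugs)]
    centers = np.eye(3) * 8.0
    vals = np.vstack(
        [centers[i % 3] + 0.05 * rng.standard_normal(3) for i in range(n_drugs)]
    )
    prof = ProfileMatrix(ids, ["x", "y", "z"], vals)
    red = fm.fit_reduce(prof, prof, d_ssp=2, d_psp=2)
    pairs = []
    for i in range(n_drugs):
        for j in range(n_drugs):
            if i != j:
                pairs.append(DDIPair(ids[i], ids[j], i % 3 + 1))
    rng.shuffle(pairs)
    return red, pairs[:200]


class TestTrain:
    CFG = dict(hidden_layers=2, hidden_nodes=64, epochs=30, n_types=3, seed=0)

    def test_separable_fixture_reaches_high_accuracy(self):
        red, pairs = separable_setup()
        model = fm.train(pairs, red, fm.ModelConfig(**self.CFG))
        preds = fm.predict_batch(model, pairs, red, threshold=0.0)
        acc = np.mean([p.predicted_type == q.ddi_type for p, q in zip(preds, pairs)])
        assert acc >= 0.95

    def test_same_seed_identical_weights(self):
        red, pairs = separable_setup()
        cfg = fm.ModelConfig(**{**self.CFG, "epochs": 5})
        m1 = fm.train(pairs, red, cfg)
        m2 = fm.train(pairs, red, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)
        assert m1.loss_trajectory == m2.loss_trajectory

    def test_zero_learning_rate_freezes_loss(self):
        red, pairs = separable_setup()
        cfg = fm.ModelConfig(**{**self.CFG, "epochs": 5, "learning_rate": 0.0})
        model = fm.train(pairs, red, cfg)
        assert len(set(model.loss_trajectory)) == 1

    def test_empty_class_warns_but_trains(self, caplog):
        red, pairs = separable_setup()
        cfg = fm.ModelConfig(**{**self.CFG, "epochs": 2, "n_types": 5})
        import logging

        with caplog.at_level(logging.WARNING):
            model = fm.train(pairs, red, cfg)
        assert "no training examples" in caplog.text
        assert model.predict_proba(fm.pair_features(pairs[0], red)).shape[1] == 5


class TestPredict:
    def make_model(self):
        red, pairs = separable_setup()
        cfg = fm.ModelConfig(hidden_layers=1, hidden_nodes=32, epochs=20,
                             n_types=3, seed=1)
        return fm.train(pairs, red, cfg), red, pairs

    def test_probabilities_sum_to_one(self):
        model, red, pairs = self.make_model()
        X = np.vstack([fm.pair_features(p, red) for p in pairs[:20]])
        probs = model.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_threshold_abstention_and_confidence_reporting(self):
        model, red, pairs = self.make_model()
        result = fm.predict(model, pairs[0], red, threshold=0.999999)
        assert result.predicted_type is None and 0.0 <= result.confidence <= 1.0
        confident = fm.predict(model, pairs[0], red, threshold=0.0)
        assert confident.predicted_type is not None
        assert confident.confidence == pytest.approx(result.confidence)

    def test_raising_threshold_never_unabstains(self):
        model, red, pairs = self.make_model()
        taus = [0.1, 0.3, 0.47, 0.6, 0.9]
        for pair in pairs[:30]:
            decided = [
                fm.predict(model, pair, red, threshold=t).predicted_type is not None
                for t in taus
            ]
            # once abstained at some tau, abstained at every higher tau
            assert decided == sorted(decided, reverse=True)

    def test_dimension_mismatch_rejected(self):
        model, red, _ = self.make_model()
        with pytest.raises(ValidationError, match="dimension"):
            model.predict_proba(np.zeros((1, 3)))


def test_checkpoint_round_trip(tmp_path):
    red, pairs = separable_setup()
    cfg = fm.ModelConfig(hidden_layers=1, hidden_nodes=16, epochs=3, n_types=3, seed=2)
    model = fm.train(pairs, red, cfg)
    path = tmp_path / "model.npz"
    fm.save_checkpoint(model, red, path)
    model2, red2 = fm.load_checkpoint(path)
    assert red2.drug_ids == red.drug_ids
    X = np.vstack([fm.pair_features(p, red) for p in pairs[:5]])
    assert np.array_equal(model.predict_proba(X), model2.predict_proba(X))
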