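"""Feature assembly, eANN training/prediction, Shapley explanations."""

import numpy as np
import pytest

import spikeconn as sc
from spikeconn.ensemble import (FEATURE_COLUMNS, assemble_features,
                                build_training_set, predict_eann,
                                shap_explain, train_eann, AssemblyError)
from spikeconn.simulate import GroundTruthNetwork
from spikeconn.spike_trains import InferenceResult

METHODS = ("CI", "sCCG", "dSTTC", "GLMCC", "TE", "GLMPP")


def fake_results(n_units=10, seed=0, nan_at=None):
    rng = np.random.default_rng(seed)
    out = []
    ids = [f"u{k}" for k in range(n_units)]
    for m in METHODS:
        S = rng.uniform(0, 5, (n_units, n_units))
        W = rng.normal(0, 1, (n_units, n_units))
        if nan_at and m == nan_at[0]:
            W[nan_at[1], nan_at[2]] = np.nan
        out.append(InferenceResult(m, S, W, ids))
    return out


def toy_network(n=10, seed=1, p=0.2):
    rng = np.random.default_rng(seed)
    adj = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(adj, 0.0)
    ei = np.array(["E"] * (n // 2) + ["I"] * (n - n // 2), dtype=object)
    adj[ei == "I"] *= -1
    return GroundTruthNetwork(n, adj, ei, p)


class TestAssembleFeatures:
    def test_shape_and_canonical_order(self):
        feats = assemble_features(fake_results())
        assert feats.X.shape == (90, 12)
        assert feats.columns == FEATURE_COLUMNS

    def test_order_invariance(self):
        results = fake_results(seed=2)
        a = assemble_features(results)
        b = assemble_features(results[::-1])
        np.testing.assert_array_equal(a.X, b.X)

    def test_missing_method_raises(self):
        with pytest.raises(AssemblyError, match="GLMPP"):
            assemble_features(fake_results()[:-1])

    def test_nan_imputed_to_column_median(self):
        results = fake_results(seed=3, nan_at=("GLMCC", 0, 1))
        feats = assemble_features(results)
        col = FEATURE_COLUMNS.index("GLMCC.w")
        W = [r for r in results if r.method == "GLMCC"][0].W
        off = ~np.eye(10, dtype=bool)
        vals = W[off]
        expected = np.median(vals[np.isfinite(vals)])
        assert feats.X[0, col] == pytest.approx(expected)
        assert np.all(np.isfinite(feats.X))


class TestBuildTrainingSet:
    def test_ten_percent_rule_arithmetic(self):
        # 60 true connections at pos_fraction 0.1 -> 600 rows, 540 negatives
        rng = np.random.default_rng(4)
        n = 26  # 650 ordered pairs
        adj = np.zeros((n, n))
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        for (i, j) in [pairs[k] for k in
                       rng.choice(len(pairs), 60, replace=False)]:
            adj[i, j] = 1.0
        ei = np.array(["E"] * n, dtype=object)
        gt = GroundTruthNetwork(n, adj, ei, 0.1)
        feats = assemble_features(fake_results(n_units=n, seed=5))
        ts = build_training_set(feats, gt, pos_fraction=0.1, seed=6)
        assert ts.labels.size == 600
        assert (ts.labels == 0).sum() == 540
        assert (ts.labels != 0).sum() == 60

    def test_balanced_fraction_and_determinism(self):
        gt = toy_network()
        feats = assemble_features(fake_results(seed=7))
        a = build_training_set(feats, gt, pos_fraction=0.5, seed=8)
        b = build_training_set(feats, gt, pos_fraction=0.5, seed=8)
        np.testing.assert_array_equal(a.features, b.features)
        assert (a.labels == 0).sum() == pytest.approx(
            (a.labels != 0).sum(), abs=1)

    def test_labels_follow_presynaptic_type(self):
        gt = toy_network(seed=9)
        feats = assemble_features(fake_results(seed=9))
        ts = build_training_set(feats, gt, pos_fraction=0.5, seed=10)
        assert set(np.unique(ts.labels)) <= {0, 1, 2}
        assert (ts.labels == 1).sum() == (gt.adjacency > 0).sum()
        assert (ts.labels == 2).sum() == (gt.adjacency < 0).sum()

    def test_insufficient_negatives_rejected(self):
        gt = toy_network(seed=11, p=0.5)
        feats = assemble_features(fake_results(seed=11))
        with pytest.raises(ValueError):
            build_training_set(feats, gt, pos_fraction=0.05, seed=12)


def separable_training_set(n=900, seed=13):
    """Three linearly separable clusters in 12-D."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, (n, 12))
    y = rng.integers(0, 3, n)
    X[y == 1, 0] += 5.0
    X[y == 2, 1] += 5.0
    from spikeconn.ensemble import TrainingSet
    return TrainingSet(features=X, labels=y)


class TestTrainPredict:
    def test_architecture_and_descent(self):
        model = train_eann([separable_training_set()], seed=0)
        assert model.layer_shapes == ((12, 10), (10, 10), (10, 3))
        loss = model.metadata["loss_curve"]
        assert loss[-1] < loss[0]

    def test_separable_accuracy(self):
        ts = separable_training_set()
        model = train_eann([ts], seed=1)
        probs = model.predict_proba(ts.features)
        acc = (np.argmax(probs, axis=1) == ts.labels).mean()
        assert acc > 0.99

    def test_probabilities_and_score_definition(self):
        ts = separable_training_set(seed=14)
        model = train_eann([ts], seed=2)
        feats = assemble_features(fake_results(seed=15))
        probs, res = predict_eann(model, feats)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(
            res.S[off], np.maximum(probs[:, 1], probs[:, 2]))
        np.testing.assert_allclose(res.W[off], probs[:, 1] - probs[:, 2])

    def test_batch_equals_rowwise(self):
        ts = separable_training_set(seed=16)
        model = train_eann([ts], seed=3)
        X = ts.features[:7]
        batch = model.predict_proba(X)
        rows = np.vstack([model.predict_proba(x) for x in X])
        np.testing.assert_allclose(batch, rows, atol=1e-12)

    def test_degenerate_single_class_rejected(self):
        from spikeconn.ensemble import TrainingSet
        ts = TrainingSet(features=np.random.rand(50, 12),
                         labels=np.zeros(50, dtype=int))
        with pytest.raises(ValueError):
            train_eann([ts], seed=4)

    def test_save_load_roundtrip(self, tmp_path):
        ts = separable_training_set(seed=17)
        model = train_eann([ts], seed=5)
        path = tmp_path / "model.h5"
        model.save(path)
        from spikeconn.ensemble import EannModel
        back = EannModel.load(path)
        X = ts.features[:20]
        np.testing.assert_allclose(back.predict_proba(X),
                                   model.predict_proba(X), atol=1e-10)


class TestShap:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(18)
        c = rng.normal(size=12)
        f = lambda X: X @ c
        x = rng.normal(size=12)
        bg = rng.normal(size=(40, 12))
        rep = shap_explain(f, x, bg, output_class=0, mode="exact")
        expected = c * (x - bg.mean(axis=0))
        np.testing.assert_allclose(rep.values, expected, atol=1e-9)

    def test_local_accuracy_exact(self):
        ts = separable_training_set(seed=19)
        model = train_eann([ts], seed=6)
        x = ts.features[0]
        bg = ts.features[10:40]
        for cls in (0, 1, 2):
            rep = shap_explain(model, x, bg, output_class=cls, mode="exact")
            assert rep.base_value + rep.values.sum() == pytest.approx(
                rep.model_output, abs=1e-6)

    def test_sampled_close_to_exact(self):
        ts = separable_training_set(seed=20)
        model = train_eann([ts], seed=7)
        x = ts.features[1]
        bg = ts.features[30:45]
        exact = shap_explain(model, x, bg, output_class=1, mode="exact")
        sampled = shap_explain(model, x, bg, output_class=1,
                               mode="sampled", seed=8,
                               n_permutations=2000)
        np.testing.assert_allclose(sampled.values, exact.values, atol=0.01)

    def test_unknown_class_rejected(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError):
            shap_explain(f, np.zeros(12), np.zeros((3, 12)),
                         output_class=7)

    def test_dummy_feature_gets_low_attribution(self):
        # a pure-noise column receives lower mean |SHAP| than the top
        # informative feature on a retrained model
        rng = np.random.default_rng(21)
        from spikeconn.ensemble import TrainingSet
        n = 900
        X = rng.normal(0, 0.3, (n, 12))
        y = rng.integers(0, 3, n)
        X[y == 1, 0] += 4.0
        X[y == 2, 1] += 4.0
        X[:, 5] = rng.normal(size=n)  # dummy
        model = train_eann([TrainingSet(features=X, labels=y)], seed=9)
        bg = X[rng.choice(n, 30, replace=False)]
        vals = []
        for k in rng.choice(n, 15, replace=False):
            rep = shap_explain(model, X[k], bg, output_class=1,
                               mode="exact")
            vals.append(np.abs(rep.values))
        mean_abs = np.mean(vals, axis=0)
        assert mean_abs[5] < mean_abs.max()
        assert np.argmax(mean_abs) == 0  # the E-separating feature
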