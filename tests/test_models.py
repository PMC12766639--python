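"""Classifier families: weights, folds, determinism, leakage, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnolstm.exceptions import TrainingError, ValidationError
from somnolstm.features import FeatureDataset
from somnolstm.models import (
    DEFAULT_GRIDS,
    DEFAULT_HYPERPARAMETERS,
    ModelConfig,
    compute_class_weights,
    cross_validate,
    grid_search,
    train_model,
)
from somnolstm.nn import LocalGlobalLSTM


class TestClassWeights:
    def test_binary_example(self):
        cw = compute_class_weights(["S", "S", "S", "W"])
        assert cw.weights["S"] == pytest.approx(4 / (2 * 3))
        assert cw.weights["W"] == pytest.approx(2.0)

    def test_balanced_labels_unit_weights(self):
        cw = compute_class_weights(["a"] * 10 + ["b"] * 10)
        assert all(w == 1.0 for w in cw.weights.values())

    def test_four_class_example(self):
        labels = ["a"] * 10 + ["b"] * 20 + ["c"] * 30 + ["d"] * 40
        cw = compute_class_weights(labels)
        assert cw.weights["a"] == pytest.approx(2.5)
        assert cw.weights["b"] == pytest.approx(1.25)
        assert cw.weights["c"] == pytest.approx(0.8333, abs=1e-4)
        assert cw.weights["d"] == pytest.approx(0.625)

    def test_missing_class_named_in_error(self):
        with pytest.raises(TrainingError, match="wake"):
            compute_class_weights(["sleep"] * 5, classes=("wake", "sleep"))

    @given(st.lists(st.sampled_from("abc"), min_size=3, max_size=200).filter(
        lambda ls: len(set(ls)) >= 2))
    @settings(max_examples=200, deadline=None)
    def test_weight_count_conservation(self, labels):
        cw = compute_class_weights(labels)
        total = sum(cw.weights[c] * cw.counts[c] for c in cw.weights)
        assert total == pytest.approx(cw.n_samples, rel=1e-12)


class TestWeightedLossIdentity:
    def test_balanced_weights_reduce_to_unweighted_loss(self):
        net = LocalGlobalLSTM(n_classes=2, n_components=4, n_channels=3,
                              local_hidden=4, hidden=5, dropout=0.0, seed=0,
                              dtype=np.float64)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 6, 4, 3))
        y = np.tile([0, 1, 0, 1, 0, 1], (2, 1))  # balanced
        l_w, _ = net.loss_and_grads(X, y, np.array([1.0, 1.0]), train=False)
        # unweighted: same computation with all-ones weights IS unweighted
        probs = [net.predict_proba_night(X[i]) for i in range(2)]
        nll = -np.log([p[np.arange(6), y[i]] for i, p in enumerate(probs)])
        assert l_w == pytest.approx(float(np.mean(nll)), rel=1e-9)


class TestGradients:
    def test_backprop_matches_numeric_gradients(self):
        net = LocalGlobalLSTM(n_classes=3, n_components=5, n_channels=4,
                              local_hidden=4, hidden=6, dropout=0.0, seed=1,
                              dtype=np.float64)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2, 3, 5, 4))
        y = rng.integers(0, 3, size=(2, 3))
        w = np.array([1.0, 2.0, 0.5])
        _, grads = net.loss_and_grads(X, y, w, train=False)
        eps = 1e-6
        flat_params = (
            [(net.params[k][k2], grads[k][k2])
             for k in ("local", "gfwd", "gbwd") for k2 in ("Wx", "Wh", "b")]
            + [(net.params["Wo"], grads["Wo"]), (net.params["bo"], grads["bo"])]
        )
        check_rng = np.random.default_rng(0)
        for arr, g in flat_params:
            flat = list(np.ndindex(arr.shape))
            for i in check_rng.choice(len(flat), min(4, len(flat)), replace=False):
                ix = flat[i]
                orig = arr[ix]
                arr[ix] = orig + eps
                lp, _ = net.loss_and_grads(X, y, w, train=False)
                arr[ix] = orig - eps
                lm, _ = net.loss_and_grads(X, y, w, train=False)
                arr[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[ix]) <= 1e-7 + 1e-4 * (abs(num) + abs(g[ix]))


@pytest.fixture(scope="module")
def lstm_model(small_datasets):
    _, seqs = small_datasets
    cfg = ModelConfig(family="lstm", task="binary",
                      hyperparameters={"hidden": 12, "lr": 1e-2,
                                       "dropout": 0.1}, seed=3)
    return train_model(cfg, seqs), seqs


class TestPredictContracts:
    def test_probabilities_sum_to_one(self, lstm_model):
        model, seqs = lstm_model
        pred = model.predict(seqs)
        p = pred[[c for c in pred.columns if c.startswith("p_")]].to_numpy()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_consistency(self, lstm_model):
        model, seqs = lstm_model
        pred = model.predict(seqs)
        pcols = [c for c in pred.columns if c.startswith("p_")]
        classes = [c[2:] for c in pcols]
        p = pred[pcols].to_numpy()
        row_max = p.max(axis=1)
        chosen = pred["pred"].map({c: i for i, c in enumerate(classes)}).to_numpy()
        assert np.allclose(p[np.arange(len(p)), chosen], row_max)

    def test_exact_tie_breaks_toward_wake(self):
        # argmax tie rule applies to the fixed class order (wake first)
        order = np.array(["wake", "sleep"], dtype=object)
        probs = np.array([[0.5, 0.5]])
        assert order[np.argmax(probs, axis=1)][0] == "wake"

    def test_same_seed_identical_predictions(self, small_datasets):
        _, seqs = small_datasets
        cfg = ModelConfig(family="lstm", task="binary",
                          hyperparameters={"hidden": 8, "lr": 1e-2,
                                           "dropout": 0.3}, seed=5)
        p1 = train_model(cfg, seqs).predict(seqs)
        p2 = train_model(cfg, seqs).predict(seqs)
        assert p1.equals(p2)


class TestGridSearch:
    def test_single_point_grid_short_circuits(self, small_datasets):
        feats, _ = small_datasets
        cfg = ModelConfig(family="logistic", task="binary", seed=0)
        out = grid_search(cfg, feats, [{"C": 0.5, "penalty": "l2"}])
        assert out == {"C": 0.5, "penalty": "l2"}

    def test_declared_grids_match_configuration_space(self):
        assert len(DEFAULT_GRIDS["logistic"]) == 14
        assert [g["max_depth"] for g in DEFAULT_GRIDS["random_forest"]] == [10, 50, 100]
        assert len(DEFAULT_GRIDS["lstm"]) == 27
        assert DEFAULT_HYPERPARAMETERS["lstm"] == {
            "hidden": 128, "lr": 1e-4, "dropout": 0.1
        }

    def test_tie_breaks_by_declaration_order(self, small_datasets):
        feats, _ = small_datasets
        cfg = ModelConfig(family="random_forest", task="binary", seed=0)
        # duplicated candidate: identical scores, first declared must win
        grid = [{"max_depth": 10, "n_estimators": 20},
                {"max_depth": 10, "n_estimators": 20}]
        out = grid_search(cfg, feats, grid)
        assert out is not grid[0] and out == grid[0]


class TestCrossValidation:
    def test_fold_partition_properties(self, small_datasets):
        feats, _ = small_datasets
        cfg = ModelConfig(family="logistic", task="binary", seed=0)
        cv = cross_validate(feats, cfg, k=3, seed=0)
        # every subject in exactly one test fold; every valid epoch once
        assert set(cv.fold_map) == set(feats.participants)
        per = cv.predictions.groupby("participant_id")["fold"].nunique()
        assert (per == 1).all()
        counts = cv.predictions.groupby("participant_id").size()
        expected = feats.df.groupby("participant_id").size()
        assert counts.sort_index().equals(expected.sort_index())

    def test_fold_assignment_reproducible(self, small_datasets):
        feats, _ = small_datasets
        cfg = ModelConfig(family="logistic", task="binary", seed=0)
        a = cross_validate(feats, cfg, k=3, seed=4)
        b = cross_validate(feats, cfg, k=3, seed=4)
        assert a.fold_map == b.fold_map
        assert a.predictions.equals(b.predictions)

    def test_k_larger_than_cohort_rejected(self, small_datasets):
        feats, _ = small_datasets
        cfg = ModelConfig(family="logistic", task="binary", seed=0)
        with pytest.raises(ValidationError):
            cross_validate(feats, cfg, k=10, seed=0)

    def test_leakage_guard(self, small_datasets):
        """Dropping a test subject's epochs must not change a fold's model."""
        feats, _ = small_datasets
        cfg = ModelConfig(family="logistic", task="binary", seed=0)
        train_ids = feats.participants[:4]
        test_ids = feats.participants[4:]
        m1 = train_model(cfg, feats.subset(train_ids))
        # rebuild the training set after deleting half of a test subject's rows
        df = feats.df
        drop = df[(df.participant_id == test_ids[0])].index[::2]
        feats2 = FeatureDataset(df.drop(drop).reset_index(drop=True))
        m2 = train_model(cfg, feats2.subset(train_ids))
        assert np.array_equal(m1.estimator.coef_, m2.estimator.coef_)
        assert np.array_equal(m1.estimator.intercept_, m2.estimator.intercept_)

    def test_epoch_level_split_option(self, small_datasets):
        feats, _ = small_datasets
        cfg = ModelConfig(family="logistic", task="binary", seed=0)
        cv = cross_validate(feats, cfg, k=4, seed=0, epoch_level=True)
        assert len(cv.predictions) == len(feats.df)
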