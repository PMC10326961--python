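"""Folds, SGD training loop, ensembling and evaluation metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mutatt.encoding import TokenizedCatalogue
from mutatt.model import ModelConfig, MutationSetClassifier
from mutatt.training import (
    EnsembleModel,
    TrainConfig,
    calibration_and_stability,
    downsampling_curve,
    ensemble_predict,
    expand_grid,
    hyperparameter_search,
    stratified_folds,
    topk_metrics,
    train,
)


class TestStratifiedFolds:
    def test_balanced_classes_split_exactly(self):
        labels = {f"s{i}": f"c{i % 24}" for i in range(24 * 20)}
        split = stratified_folds(labels, k=10, seed=0)
        for fold in split.folds:
            counts = {}
            for s in fold:
                counts[labels[s]] = counts.get(labels[s], 0) + 1
            assert all(v == 2 for v in counts.values())

    def test_partition_and_per_class_balance(self):
        rng = np.random.default_rng(0)
        labels = {f"s{i}": f"c{rng.integers(0, 3)}" for i in range(47)}
        split = stratified_folds(labels, k=5, seed=1)
        all_samples = [s for fold in split.folds for s in fold]
        assert sorted(all_samples) == sorted(labels)
        for cls in set(labels.values()):
            sizes = [sum(labels[s] == cls for s in fold) for fold in split.folds]
            assert max(sizes) - min(sizes) <= 1

    def test_one_sample_per_fold_when_class_size_equals_k(self):
        labels = {f"s{i}": "only" for i in range(10)}
        split = stratified_folds(labels, k=10, seed=0)
        assert all(len(f) == 1 for f in split.folds)

    def test_deterministic_given_seed(self):
        labels = {f"s{i}": f"c{i % 4}" for i in range(40)}
        assert stratified_folds(labels, 10, 3).folds == stratified_folds(labels, 10, 3).folds

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds({"a": "x", "b": "x"}, k=1, seed=0)


def _toy_data(rng, n_per_class, l, n_motifs=30, n_pos=8, class_tokens=None):
    """Two-class toy cohort whose classes use disjoint motif tokens."""
    cats = []
    for label, lo, hi in class_tokens or [("a", 2, 16), ("b", 16, 30)]:
        for i in range(n_per_class):
            cats.append(TokenizedCatalogue(
                f"{label}{i}",
                rng.integers(lo, hi, l),
                rng.integers(2, n_pos, l),
                np.zeros(l, dtype=np.int64),
                np.zeros(l, dtype=bool),
                label,
            ))
    return cats


def _toy_config(**kw):
    defaults = dict(
        n_classes=2, dict_sizes={"motif": 30, "position": 8, "annotation": 18},
        embedding_dim=16, n_encoder_layers=1, n_heads=1, n_fc_layers=1,
        max_mutations=100, modalities=("motif", "position"), class_labels=["a", "b"],
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestTrain:
    def test_zero_epochs_returns_initialized_model_at_chance(self):
        rng = np.random.default_rng(0)
        data = _toy_data(rng, 5, 20)
        result = train(_toy_config(), data, data, TrainConfig(epochs=0, seed=0))
        # zero-init head: uniform logits, argmax is class 0, i.e. chance level
        assert result.best_val_accuracy == pytest.approx(0.5)

    def test_tiny_model_overfits_small_separable_set(self):
        rng = np.random.default_rng(1)
        data = _toy_data(rng, 5, 20)
        result = train(_toy_config(embedding_dim=32),
                       data, data, TrainConfig(epochs=200, seed=1))
        assert result.best_val_accuracy == 1.0
        assert result.history["train_loss"].iloc[-1] < 0.1

    def test_initial_loss_is_log_n_classes(self):
        rng = np.random.default_rng(2)
        data = _toy_data(rng, 3, 10)
        model = MutationSetClassifier(_toy_config(), seed=0)
        loss, _, _ = model.loss_and_grads(data[0].tokens(), 0)
        assert loss == pytest.approx(math.log(2))

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(minibatch_size=4)


class TestHyperparameterSearch:
    def test_single_config_wins_every_fold(self):
        rng = np.random.default_rng(3)
        data = _toy_data(rng, 6, 15)
        labels = {tc.sample_id: tc.class_label for tc in data}
        split = stratified_folds(labels, k=2, seed=0)
        by_id = {tc.sample_id: tc for tc in data}
        ensemble, report = hyperparameter_search(
            [{"embedding_dim": 16}], by_id, split, _toy_config(),
            TrainConfig(epochs=3, seed=0),
        )
        assert ensemble.n_components == 2
        assert len(report) == 2
        assert (report["embedding_dim"] == 16).all()

    def test_full_grid_cardinality_is_36(self):
        from mutatt.training import DEFAULT_GRID

        assert len(expand_grid(DEFAULT_GRID)) == 36

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_search([], {}, stratified_folds({"a": "x", "b": "x"}, 2, 0),
                                  _toy_config())


def _constant_model(logits):
    """A model whose output is exactly `logits` for any input (zero weights)."""
    cfg = _toy_config(n_classes=len(logits), class_labels=[str(i) for i in range(len(logits))])
    model = MutationSetClassifier(cfg, seed=0)
    for name in model.params:
        model.params[name] = np.zeros_like(model.params[name])
    model.params["head_b"] = np.asarray(logits, dtype=float)
    return model


class TestEnsemble:
    def _catalogue(self, rng):
        return TokenizedCatalogue("s", rng.integers(2, 30, 10), rng.integers(2, 8, 10),
                                  np.zeros(10, dtype=np.int64), np.zeros(10, dtype=bool), "0")

    def test_ensemble_of_one_equals_component(self):
        rng = np.random.default_rng(4)
        cfg = _toy_config()
        model = MutationSetClassifier(cfg, seed=5, head_init="normal")
        cat = _toy_data(rng, 1, 10)[0]
        single = EnsembleModel([model])
        pred, features = ensemble_predict(single, cat, seed=0)
        direct, _ = model.logits(cat.tokens())
        assert np.allclose(pred.logits, direct)
        assert np.allclose(features, direct)

    def test_logit_sum_decides_prediction(self):
        rng = np.random.default_rng(6)
        m1 = _constant_model([1.0, 0.0])
        m2 = _constant_model([0.0, 2.0])
        ensemble = EnsembleModel([m1, m2])
        pred, features = ensemble_predict(ensemble, self._catalogue(rng), seed=0)
        assert np.allclose(pred.logits, [1.0, 2.0])
        assert pred.predicted_index == 1
        assert np.allclose(features, [1.0, 0.0, 0.0, 2.0])

    def test_feature_length_is_components_times_classes(self):
        rng = np.random.default_rng(7)
        labels = [str(i) for i in range(24)]
        cfg = _toy_config(n_classes=24, class_labels=labels)
        components = [MutationSetClassifier(cfg, seed=s, head_init="normal") for s in range(10)]
        ensemble = EnsembleModel(components)
        cat = TokenizedCatalogue("s", rng.integers(2, 30, 10), rng.integers(2, 8, 10),
                                 np.zeros(10, dtype=np.int64), np.zeros(10, dtype=bool), "0")
        _, features = ensemble_predict(ensemble, cat, seed=0)
        assert features.shape == (240,)

    def test_mismatched_class_sets_rejected(self):
        a = MutationSetClassifier(_toy_config(), seed=0)
        b = MutationSetClassifier(_toy_config(class_labels=["x", "y"]), seed=0)
        with pytest.raises(ValueError):
            EnsembleModel([a, b])


class TestTopkMetrics:
    def test_all_correct(self):
        scores = np.eye(3)
        m = topk_metrics(scores, [0, 1, 2])
        assert m["accuracy"] == 1.0
        assert np.allclose(m["f1"], 1.0)

    def test_topk_equals_one_when_k_is_n_classes(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=(20, 4))
        m = topk_metrics(scores, rng.integers(0, 4, 20), k_list=[4])
        assert m["topk"][4] == 1.0

    def test_hand_counted_two_class_confusion(self):
        scores = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]])
        m = topk_metrics(scores, [0, 1, 1], k_list=[1])
        assert m["accuracy"] == pytest.approx(2 / 3)
        assert m["confusion_matrix"].tolist() == [[1, 0], [1, 1]]
        # precision TP/(TP+FP), recall TP/(TP+FN) per the printed formulas
        assert m["precision"][0] == pytest.approx(1 / 2)
        assert m["recall"][0] == pytest.approx(1.0)
        assert m["f1"][1] == pytest.approx(2 * 1 / (2 * 1 + 0 + 1))

    def test_never_predicted_class_flagged(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2]])
        m = topk_metrics(scores, [0, 1], k_list=[1])
        assert 1 in m["undefined_precision"]
        assert m["precision"][1] == 0.0

    def test_topk_monotone_in_k(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(50, 6))
        labels = rng.integers(0, 6, 50)
        m = topk_metrics(scores, labels, k_list=[1, 2, 3, 4, 5, 6])
        accs = [m["topk"][k] for k in (1, 2, 3, 4, 5, 6)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))

    def test_agrees_with_sklearn_confusion(self):
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(10)
        scores = rng.normal(size=(40, 5))
        labels = rng.integers(0, 5, 40)
        m = topk_metrics(scores, labels, k_list=[1])
        sk = confusion_matrix(labels, scores.argmax(axis=1), labels=range(5))
        assert np.array_equal(m["confusion_matrix"], sk)


class TestCalibrationAndStability:
    def test_confident_correct_predictions_fill_top_bin(self):
        probs = np.tile([0.99, 0.01], (10, 1))
        out = calibration_and_stability(probs, [0] * 10)
        top = out["calibration"].iloc[-1]
        assert top["count"] == 10 and top["accuracy"] == 1.0

    def test_miscalibrated_predictor_shows_gap(self):
        # constructed fixture: confidence 0.9, accuracy 0.5
        probs = np.tile([0.9, 0.1], (20, 1))
        labels = [0] * 10 + [1] * 10
        out = calibration_and_stability(probs, labels)
        row = out["calibration"][out["calibration"]["count"] > 0].iloc[-1]
        assert row["mean_confidence"] - row["accuracy"] == pytest.approx(0.4)

    def test_stability_is_one_without_subsampling_randomness(self):
        repeats = np.tile([[2]], (5, 7))
        out = calibration_and_stability(np.tile([0.6, 0.4], (5, 1)), [0] * 5,
                                        repeat_predictions=repeats)
        assert np.allclose(out["stability"], 1.0)


def test_downsampling_matches_full_evaluation_when_n_is_large():
    rng = np.random.default_rng(11)
    data = _toy_data(rng, 4, 15)
    model = MutationSetClassifier(_toy_config(), seed=12, head_init="normal")
    ensemble = EnsembleModel([model])
    curve = downsampling_curve(ensemble, data, n_list=[15, 1000], seed=0, k_list=[1])
    assert curve.loc[curve["n"] == 1000, "top1"].iloc[0] == pytest.approx(
        curve.loc[curve["n"] == 15, "top1"].iloc[0]
    )
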