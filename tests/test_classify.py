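"""Training protocol, evaluation, max-voting ensemble."""

import warnings

import numpy as np
import pytest

from holoplankton import (
    ConfusionMatrix,
    ImageDataset,
    PredictionSet,
    TrainConfig,
    ensemble_predict,
    evaluate,
    max_vote,
    select_ensemble,
    train_model,
)
from holoplankton.classify import early_stop_epoch


def toy_dataset(n_per_class=40, size=24, seed=0, values=(0.0, 2.0), class_ids=None):
    """Trivially separable constant-phase images, one value per class."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    ids = class_ids or tuple(range(1, len(values) + 1))
    for cid, v in zip(ids, values):
        for _ in range(n_per_class):
            img = np.full((size, size), v) + rng.normal(0, 0.05, (size, size))
            images.append(np.clip(img, -np.pi, np.pi - 1e-6))
            labels.append(cid)
    return ImageDataset(np.stack(images), np.array(labels), ids)


def brute_force_vote(labels, confs):
    """Oracle: per-sample mode; ties by mean confidence, then lowest id."""
    k, n = labels.shape
    out = np.empty(n, dtype=int)
    for j in range(n):
        tally = {}
        for i in range(k):
            lab = labels[i, j]
            tally.setdefault(lab, []).append(confs[i, j])
        best = None
        for lab, cs in tally.items():
            key = (len(cs), np.mean(cs), -lab)
            if best is None or key > best[0]:
                best = (key, lab)
        out[j] = best[1]
    return out


class TestMaxVote:
    def test_majority_wins(self):
        labels = np.array([[27], [27], [41]])
        assert max_vote(labels)[0] == 27

    def test_single_model_identity(self):
        labels = np.array([[3, 1, 4, 1, 5]])
        np.testing.assert_array_equal(max_vote(labels), labels[0])

    def test_all_distinct_highest_confidence_wins(self):
        labels = np.array([[1], [2], [3]])
        confs = np.array([[0.5], [0.9], [0.4]])
        assert max_vote(labels, confs)[0] == 2

    def test_remaining_tie_lowest_class_id(self):
        labels = np.array([[5], [9]])
        confs = np.array([[0.7], [0.7]])
        assert max_vote(labels, confs)[0] == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 6))
        n = int(rng.integers(1, 101))
        labels = rng.integers(0, 8, size=(k, n))
        confs = rng.random((k, n)).round(3)
        np.testing.assert_array_equal(
            max_vote(labels, confs), brute_force_vote(labels, confs)
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            max_vote(np.zeros((2, 3), int), np.zeros((2, 4)))

    def test_voted_label_among_member_labels(self):
        rng = np.random.default_rng(0)
        ps = PredictionSet(
            per_model_labels=rng.integers(0, 5, (4, 50)),
            per_model_confidences=rng.random((4, 50)),
        )
        for j in range(50):
            assert ps.voted_labels[j] in ps.per_model_labels[:, j]


class TestSelectEnsemble:
    def test_threshold_selects_three_of_four(self):
        results = [("a", 0.91), ("b", 0.94), ("c", 0.88), ("d", 0.95)]
        sel = select_ensemble(results, threshold=0.90)
        assert [name for name, _ in sel] == ["a", "b", "d"]

    def test_impossible_threshold_warns_and_returns_empty(self):
        with pytest.warns(RuntimeWarning, match="threshold"):
            sel = select_ensemble([("a", 0.9)], threshold=1.0)
        assert sel == []

    def test_zero_threshold_selects_all(self):
        results = [("a", 0.5), ("b", 0.1)]
        assert select_ensemble(results, threshold=0.0) == results


class TestEarlyStopping:
    def test_stops_exactly_patience_epochs_after_best(self):
        losses = [1.0, 0.8, 0.7, 0.71, 0.72, 0.73, 0.74, 0.75, 0.9, 0.9]
        best, stop = early_stop_epoch(losses, patience=5)
        assert best == 2
        assert stop == 7  # best + patience

    def test_no_stop_when_improving(self):
        losses = [1.0, 0.9, 0.8, 0.7, 0.6]
        best, stop = early_stop_epoch(losses, patience=5)
        assert best == 4
        assert stop == 4  # ran to the end

    def test_plateau_counts_as_no_improvement(self):
        losses = [1.0, 1.0, 1.0, 1.0]
        best, stop = early_stop_epoch(losses, patience=3)
        assert best == 0
        assert stop == 3


class TestTrainModel:
    def test_separable_toy_reaches_perfect_validation(self):
        train_ds = toy_dataset(40, seed=0)
        val_ds = toy_dataset(10, seed=1)
        cfg = TrainConfig(learning_rate=0.01, crop_px=24, max_epochs=20, batch_size=16, seed=0)
        model = train_model(train_ds, val_ds, "tiny_cnn", cfg)
        res = evaluate(model, val_ds)
        assert res.accuracy == 1.0

    def test_training_is_deterministic(self):
        train_ds = toy_dataset(20, seed=0)
        val_ds = toy_dataset(5, seed=1)
        cfg = TrainConfig(learning_rate=0.01, crop_px=24, max_epochs=6,
                          patience_epochs=2, batch_size=16, seed=7)
        m1 = train_model(train_ds, val_ds, "tiny_cnn", cfg)
        m2 = train_model(train_ds, val_ds, "tiny_cnn", cfg)
        assert m1.log.val_losses == m2.log.val_losses
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])

    def test_trainer_applies_early_stop_rule(self):
        """The live trainer stops at the epoch the pure rule predicts."""
        train_ds = toy_dataset(20, seed=0)
        val_ds = toy_dataset(5, seed=1)
        cfg = TrainConfig(
            learning_rate=0.01, crop_px=24, max_epochs=30, patience_epochs=2,
            batch_size=16, seed=0,
        )
        model = train_model(train_ds, val_ds, "tiny_cnn", cfg)
        best, stop = early_stop_epoch(model.log.val_losses, patience=2)
        assert model.log.best_epoch == best
        assert model.log.stopped_epoch == stop

    def test_best_checkpoint_is_restored(self):
        train_ds = toy_dataset(20, seed=0)
        val_ds = toy_dataset(5, seed=1)
        cfg = TrainConfig(
            learning_rate=0.01, crop_px=24, max_epochs=25, patience_epochs=3,
            batch_size=16, seed=0,
        )
        model = train_model(train_ds, val_ds, "tiny_cnn", cfg)
        assert model.log.best_epoch >= 0
        assert min(model.log.val_losses) == model.log.val_losses[model.log.best_epoch]

    def test_unknown_architecture_raises(self):
        ds = toy_dataset(4)
        with pytest.raises(ValueError, match="unknown architecture"):
            train_model(ds, ds, "resnet50")

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(patience_epochs=10, max_epochs=10)


class TestEvaluate:
    def _perfect_setup(self):
        train_ds = toy_dataset(40, seed=0)
        val_ds = toy_dataset(10, seed=1)
        cfg = TrainConfig(learning_rate=0.01, crop_px=24, max_epochs=20, batch_size=16, seed=0)
        model = train_model(train_ds, val_ds, "tiny_cnn", cfg)
        test_ds = toy_dataset(8, seed=2)
        return model, test_ds

    def test_perfect_predictor_diagonal_matrix(self):
        model, test_ds = self._perfect_setup()
        res = evaluate(model, test_ds)
        assert res.accuracy == 1.0
        assert np.all(res.confusion.counts == np.diag([8, 8]))

    def test_row_sums_equal_per_class_counts(self):
        model, test_ds = self._perfect_setup()
        res = evaluate(model, test_ds)
        np.testing.assert_array_equal(res.confusion.counts.sum(axis=1), [8, 8])
        assert res.confusion.total == len(test_ds)

    def test_unknown_test_label_raises(self):
        model, _ = self._perfect_setup()
        bad = toy_dataset(2, values=(0.0, 2.0), class_ids=(1, 99))
        with pytest.raises(ValueError, match="unknown"):
            evaluate(model, bad)


class TestConfusionMatrix:
    def test_restriction_preserves_counts_for_in_subset_predictions(self):
        true = np.array([1, 1, 2, 2, 3, 3])
        pred = np.array([1, 2, 2, 2, 3, 3])
        cm = ConfusionMatrix.from_predictions(true, pred, (1, 2, 3, 4, 5))
        sub = cm.restrict((1, 2, 3))
        assert sub.counts.shape == (3, 3)
        assert sub.total == cm.total == 6

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.zeros((2, 3), int), (1, 2))


class TestEnsemble:
    def test_agreement_subset_property(self):
        """Where all members agree, the ensemble equals every member, so it
        cannot be worse than the worst member on that subset."""
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(3, 200))
        agree = labels[0] == labels[1]
        agree &= labels[1] == labels[2]
        voted = max_vote(labels, rng.random((3, 200)))
        np.testing.assert_array_equal(voted[agree], labels[0][agree])

    def test_ensemble_predict_combines_models(self):
        train_ds = toy_dataset(30, seed=0)
        val_ds = toy_dataset(8, seed=1)
        cfg = TrainConfig(learning_rate=0.01, crop_px=24, max_epochs=10, batch_size=16, seed=0)
        models = [
            train_model(train_ds, val_ds, name, cfg)
            for name in ("tiny_cnn", "tiny_cnn_narrow")
        ]
        ps = ensemble_predict(models, val_ds)
        assert ps.per_model_labels.shape == (2, len(val_ds))
        acc = (ps.voted_labels == val_ds.labels).mean()
        assert acc == 1.0
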