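"""Fold plans, class weighting, metrics and the training loop."""

import numpy as np
import pandas as pd
import pytest

from eegannot.dataset import SegmentDataset
from eegannot.errors import ConfigError
from eegannot.network import ArchSpec, ConvSpec, FCSpec, PoolSpec, build_model
from eegannot.train import (
    ASGD,
    TrainConfig,
    class_weights,
    evaluate,
    make_folds,
    metrics_from_counts,
    metrics_from_probabilities,
    train_cv,
    train_final,
    weighted_cross_entropy,
)

SMALL_ARCH = ArchSpec(
    input_shape=(4, 10, 12),
    layers=(
        ConvSpec(8, 4, (1, 3)),
        PoolSpec((2, 2)),
        ConvSpec(12, 2, (3, 3)),
        PoolSpec((1, 1)),
        FCSpec(2, bias=False),
    ),
)


def toy_dataset(rng, n_subjects=10, per_subject=8, shape=(4, 10, 12)):
    """Separable toy dataset: artifact tensors carry a strong pattern shift."""
    rows, tensors = [], []
    for s in range(n_subjects):
        for i in range(per_subject):
            label = "artifact" if i % 2 == 0 else "nonartifact"
            x = rng.standard_normal(shape).astype(np.float32)
            if label == "artifact":
                x[:, : shape[1] // 2] += 2.0
            rows.append(
                {"segment_id": f"S{s:03d}R00:{i:08d}", "recording_id": f"S{s:03d}R00",
                 "subject_id": f"S{s:03d}", "onset_s": i * 0.5, "label": label}
            )
            tensors.append(x)
    return SegmentDataset(pd.DataFrame(rows), np.stack(tensors), pd.DataFrame())


class TestMakeFolds:
    def test_ten_subjects_five_folds_one_val_one_test(self):
        plan = make_folds([f"S{i}" for i in range(10)], k=5, seed=0)
        for fold in plan.folds:
            assert len(fold["val"]) == 1 and len(fold["test"]) == 1
            assert len(fold["train"]) == 8

    def test_holdouts_partition_subjects_and_tests_disjoint(self):
        subjects = [f"S{i}" for i in range(13)]
        plan = make_folds(subjects, k=5, seed=1)
        holdout = [s for f in plan.folds for s in f["val"] + f["test"]]
        assert sorted(holdout) == sorted(subjects)
        tests = [s for f in plan.folds for s in f["test"]]
        assert len(tests) == len(set(tests))

    def test_same_seed_identical_plan(self):
        s = [f"S{i}" for i in range(10)]
        assert make_folds(s, seed=3) == make_folds(s, seed=3)
        assert make_folds(s, seed=3) != make_folds(s, seed=4)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigError):
            make_folds(["a", "b", "c"], k=5)


class TestClassWeights:
    def test_inverse_frequency_rule(self):
        w = class_weights(["artifact"] * 100 + ["nonartifact"] * 300)
        assert w["artifact"] == pytest.approx(1 / 100)
        assert w["nonartifact"] == pytest.approx(1 / 300)

    def test_balanced_gives_equal(self):
        w = class_weights(["artifact", "nonartifact"] * 5)
        assert w["artifact"] == w["nonartifact"]

    def test_empty_class_rejected(self):
        with pytest.raises(ConfigError):
            class_weights(["artifact"] * 10)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss_any_weights(self):
        logits = np.array([[20.0, -20.0], [-20.0, 20.0]])
        y = np.array([0, 1])
        for w in ([1.0, 1.0], [0.01, 5.0]):
            loss, _ = weighted_cross_entropy(logits, y, np.array(w))
            assert loss == pytest.approx(0.0, abs=1e-8)

    def test_equal_weights_match_unweighted_mean(self, rng):
        logits = rng.standard_normal((16, 2))
        y = rng.integers(0, 2, 16)
        loss_w, _ = weighted_cross_entropy(logits, y, np.array([3.0, 3.0]))
        logp = logits - np.log(np.exp(logits).sum(1, keepdims=True))
        loss_plain = -logp[np.arange(16), y].mean()
        assert loss_w == pytest.approx(loss_plain, rel=1e-9)

    def test_gradient_is_softmax_minus_onehot_weighted(self):
        logits = np.array([[0.3, -0.2]])
        y = np.array([1])
        w = np.array([1.0, 2.0])
        _, grad = weighted_cross_entropy(logits, y, w)
        p = np.exp(logits[0]) / np.exp(logits[0]).sum()
        expected = (p - np.array([0.0, 1.0])) * 2.0 / 2.0
        assert np.allclose(grad[0], expected, atol=1e-6)


class TestMetrics:
    def test_hand_counted_example(self):
        m = metrics_from_counts(tp=3, fn=1, fp=1, tn=3)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.75)
        assert m.bacc == pytest.approx(0.75)

    def test_perfect_classifier(self):
        m = metrics_from_probabilities(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.1, 0.2]))
        assert (m.sensitivity, m.specificity, m.precision, m.bacc) == (1, 1, 1, 1)

    def test_all_artifact_predictor(self):
        m = metrics_from_probabilities(np.array([1, 0, 0, 1]), np.array([0.9, 0.9, 0.9, 0.9]))
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.bacc == 0.5

    def test_threshold_is_geq(self):
        m = metrics_from_probabilities(np.array([1]), np.array([0.5]))
        assert m.tp == 1  # p = 0.5 counts as artifact

    def test_no_positives_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = metrics_from_counts(tp=0, fn=0, fp=1, tn=3)
        assert np.isnan(m.sensitivity)

    def test_bacc_equals_mean_of_recalls(self, rng):
        y = rng.integers(0, 2, 100)
        p = rng.random(100)
        m = metrics_from_probabilities(y, p)
        recall_pos = m.tp / (m.tp + m.fn)
        recall_neg = m.tn / (m.tn + m.fp)
        assert m.bacc == (recall_pos + recall_neg) / 2


class TestASGD:
    def test_plain_sgd_before_averaging_kicks_in(self):
        p = np.array([1.0], np.float32)
        opt = ASGD([p], lr=0.1, lambd=0.0)
        opt.step([np.array([2.0], np.float32)])
        assert p[0] == pytest.approx(1.0 - 0.1 * 2.0)

    def test_step_size_anneals(self):
        p = np.array([0.0], np.float32)
        opt = ASGD([p], lr=0.1, lambd=1e-2, alpha=0.75)
        g = [np.array([1.0], np.float32)]
        opt.step(g)
        assert opt.eta < 0.1


class TestTrainingLoops:
    def test_cv_on_separable_toy_data(self, rng):
        ds = toy_dataset(rng)
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, epochs_cv=3,
                          epochs_final=3, seed=0)
        plan = make_folds(ds.segments["subject_id"], k=5, seed=0)
        cv = train_cv(ds, plan, cfg, arch=SMALL_ARCH)
        assert len(cv.folds) == 5
        for f in cv.folds:
            assert {"epoch", "train_loss", "val_loss"} <= set(f.history.columns)
        assert cv.pooled_metrics.bacc > 0.9

    def test_cv_is_deterministic(self, rng):
        ds = toy_dataset(rng, n_subjects=5, per_subject=4)
        cfg = TrainConfig(batch_size=4, learning_rate=0.05, epochs_cv=2, seed=9)
        plan = make_folds(ds.segments["subject_id"], k=5, seed=9)
        cv1 = train_cv(ds, plan, cfg, arch=SMALL_ARCH)
        cv2 = train_cv(ds, plan, cfg, arch=SMALL_ARCH)
        pd.testing.assert_frame_equal(cv1.folds[0].predictions, cv2.folds[0].predictions)

    def test_final_training_covers_every_segment_once(self, rng):
        ds = toy_dataset(rng, n_subjects=4, per_subject=6)
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, epochs_final=3, seed=1)
        model, preds = train_final(ds, cfg, arch=SMALL_ARCH)
        assert sorted(preds["segment_id"]) == sorted(ds.segments["segment_id"])
        assert preds["segment_id"].is_unique

    def test_final_training_loss_collapses_on_separable_data(self, rng):
        ds = toy_dataset(rng, n_subjects=4, per_subject=6)
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, epochs_final=20, seed=1)
        model, _ = train_final(ds, cfg, arch=SMALL_ARCH)
        hist = model.history
        assert hist["train_loss"].iloc[-1] < 0.1 * hist["train_loss"].iloc[0]

    def test_prediction_table_roundtrips_through_io(self, rng, tmp_path):
        from eegannot.io import read_table, write_table

        ds = toy_dataset(rng, n_subjects=4, per_subject=4)
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, epochs_final=2, seed=1)
        _, preds = train_final(ds, cfg, arch=SMALL_ARCH)
        write_table(preds, tmp_path / "p.csv")
        back = read_table(tmp_path / "p.csv")
        pd.testing.assert_frame_equal(back, preds)

    def test_single_batch_overfit_full_architecture(self, rng):
        """Capacity sanity check: the full network memorizes a small batch."""
        n = 8
        x = rng.standard_normal((n, 19, 45, 100)).astype(np.float32)
        y_labels = ["artifact" if i % 2 else "nonartifact" for i in range(n)]
        x[[i for i, l in enumerate(y_labels) if l == "artifact"], :, :20] += 1.0
        rows = pd.DataFrame({
            "segment_id": [f"r:{i}" for i in range(n)],
            "recording_id": "r", "subject_id": "s",
            "onset_s": np.arange(n) * 0.5, "label": y_labels,
        })
        ds = SegmentDataset(rows, x, pd.DataFrame())
        cfg = TrainConfig(batch_size=2, learning_rate=0.002, epochs_final=20, seed=2)
        model, preds = train_final(ds, cfg)
        y = (np.array(y_labels) == "artifact").astype(int)
        acc = ((preds["p_artifact"].to_numpy() >= 0.5).astype(int) == y).mean()
        assert acc == 1.0


def test_evaluate_matches_probability_path(rng):
    model = build_model(SMALL_ARCH, seed=0)
    x = rng.standard_normal((6, 4, 10, 12)).astype(np.float32)
    labels = ["artifact", "nonartifact"] * 3
    m1 = evaluate(model, x, labels)
    p = model.predict_proba(x)[:, 1]
    m2 = metrics_from_probabilities((np.array(labels) == "artifact").astype(int), p)
    assert m1 == m2
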