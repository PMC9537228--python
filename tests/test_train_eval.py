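import numpy as np
import pytest

from gaitstream import (
    FusionNetConfig,
    GaitSimParams,
    MixupSpec,
    NormalizationConfig,
    TrainConfig,
    compute_metrics,
    cross_validate,
    generate_cohort,
    normalize,
    stratified_kfold,
    train_fold,
)
from gaitstream.io import CLASSES
from gaitstream.metrics import aggregate_reports
from gaitstream.train import featurize_set


def brute_force_prf(y_true, y_pred, n_classes):
    """Independent oracle for precision/recall/F1 from first principles."""
    precision, recall, f1 = [], [], []
    for k in range(n_classes):
        tp = int(np.sum((y_true == k) & (y_pred == k)))
        fp = int(np.sum((y_true != k) & (y_pred == k)))
        fn = int(np.sum((y_true == k) & (y_pred != k)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(f)
    return np.array(precision), np.array(recall), np.array(f1)


def brute_force_auc(scores, is_positive):
    """AUC as the probability a positive outranks a negative (tie = 1/2)."""
    pos = scores[is_positive]
    neg = scores[~is_positive]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def tiny_cohort():
    params = GaitSimParams(n_frames_raw=40)
    counts = {"healthy": 4, "joint_problem": 4, "muscle_weakness": 4,
              "neurological_defect": 4}
    cohort = generate_cohort(params, counts, seed=11)
    return [normalize(s, NormalizationConfig(t_target=20)) for s in cohort]


TINY_MODEL = FusionNetConfig(t_frames=20, post_fusion_channels=(4, 8))


class TestStratifiedKFold:
    def test_45_samples_gives_folds_of_9(self):
        labels = (
            ["healthy"] * 10 + ["joint_problem"] * 4 + ["muscle_weakness"] * 18
            + ["neurological_defect"] * 13
        )
        with pytest.warns(UserWarning, match="least populated"):
            folds = stratified_kfold(labels, 5, seed=3)
        assert len(folds) == 5
        for _, test_idx in folds:
            assert len(test_idx) == 9

    def test_partition_property(self):
        labels = ["healthy"] * 12 + ["muscle_weakness"] * 8
        folds = stratified_kfold(labels, 4, seed=0)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(20))
        for train_idx, test_idx in folds:
            assert set(train_idx).isdisjoint(test_idx)
            assert sorted(np.concatenate([train_idx, test_idx])) == list(range(20))

    def test_scarce_class_pigeonhole_warns(self):
        labels = ["healthy"] * 16 + ["joint_problem"] * 4
        with pytest.warns(UserWarning, match="4 members"):
            folds = stratified_kfold(labels, 5, seed=1)
        jp_indices = set(range(16, 20))
        missing = [
            fold_id for fold_id, (_, test_idx) in enumerate(folds)
            if not jp_indices & set(test_idx)
        ]
        assert len(missing) >= 1

    def test_determinism(self):
        labels = ["healthy"] * 10 + ["muscle_weakness"] * 10
        a = stratified_kfold(labels, 5, seed=7)
        b = stratified_kfold(labels, 5, seed=7)
        for (tr_a, te_a), (tr_b, te_b) in zip(a, b):
            np.testing.assert_array_equal(te_a, te_b)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError, match="k must"):
            stratified_kfold(["healthy"] * 10, 1)
        with pytest.raises(ValueError, match="k must"):
            stratified_kfold(["healthy"] * 10, 11)


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([0, 1, 2, 3, 0, 1])
        proba = np.eye(4)[y]
        rep = compute_metrics(y, proba)
        assert rep.macro["overall_accuracy"] == 1.0
        assert np.all(rep.per_class["f1"] == 1.0)
        assert np.all(rep.confusion == np.diag(np.bincount(y, minlength=4)))

    def test_toy_binary_confusion_hand_arithmetic(self):
        # confusion [[9,1],[2,8]]: recall_0 = 0.9, precision_0 = 9/11
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.array([0] * 9 + [1] + [0] * 2 + [1] * 8)
        proba = np.zeros((20, 4))
        proba[np.arange(20), y_pred] = 1.0
        rep = compute_metrics(y_true, proba)
        np.testing.assert_array_equal(rep.confusion[:2, :2], [[9, 1], [2, 8]])
        assert rep.per_class["recall"][0] == pytest.approx(0.9)
        assert rep.per_class["precision"][0] == pytest.approx(9 / 11)

    def test_prf_matches_brute_force(self, rng):
        for _ in range(10):
            y_true = rng.integers(0, 4, size=30)
            proba = rng.dirichlet(np.ones(4), size=30)
            rep = compute_metrics(y_true, proba)
            p, r, f = brute_force_prf(y_true, proba.argmax(axis=1), 4)
            np.testing.assert_allclose(rep.per_class["precision"], p, atol=1e-12)
            np.testing.assert_allclose(rep.per_class["recall"], r, atol=1e-12)
            np.testing.assert_allclose(rep.per_class["f1"], f, atol=1e-12)

    def test_auc_matches_rank_statistic(self, rng):
        y_true = rng.integers(0, 4, size=60)
        proba = rng.dirichlet(np.ones(4), size=60)
        rep = compute_metrics(y_true, proba)
        for k in range(4):
            want = brute_force_auc(proba[:, k], y_true == k)
            assert rep.per_class["auc"][k] == pytest.approx(want, abs=1e-9)

    def test_random_scorer_auc_near_half(self, rng):
        n = 4000
        y_true = rng.integers(0, 4, size=n)
        proba = rng.dirichlet(np.ones(4), size=n)  # independent of labels
        rep = compute_metrics(y_true, proba)
        np.testing.assert_allclose(rep.per_class["auc"], 0.5, atol=0.05)

    def test_missing_class_auc_nan_with_warning(self):
        y_true = np.array([0, 0, 1, 1])
        proba = np.full((4, 4), 0.25)
        with pytest.warns(UserWarning):
            rep = compute_metrics(y_true, proba)
        assert np.isnan(rep.per_class["auc"][3])

    def test_macro_vs_overall_distinct_on_imbalanced(self):
        # 9/10 correct in a big class, 0/2 in a small one
        y_true = np.array([0] * 10 + [1] * 2)
        y_pred = np.array([0] * 9 + [1] + [0] * 2)
        proba = np.zeros((12, 4))
        proba[np.arange(12), y_pred] = 1.0
        with pytest.warns(UserWarning):
            rep = compute_metrics(y_true, proba)
        assert rep.macro["overall_accuracy"] == pytest.approx(9 / 12)
        assert rep.macro["macro_accuracy"] == pytest.approx((0.9 + 0.0) / 2)
        assert rep.macro["overall_accuracy"] != rep.macro["macro_accuracy"]


class TestTrainFold:
    def test_loss_log_length_one_epoch(self, tiny_cohort):
        model, log = train_fold(
            tiny_cohort[:4], TINY_MODEL, TrainConfig(epochs=1, batch_size=4, seed=0)
        )
        assert len(log) == 1
        assert "train_loss" in log[0]

    def test_loss_decreases_on_separable_toy(self, tiny_cohort):
        _, log = train_fold(
            tiny_cohort, TINY_MODEL, TrainConfig(epochs=30, batch_size=8, seed=1)
        )
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_determinism(self, tiny_cohort):
        cfg = TrainConfig(epochs=3, batch_size=8, seed=5)
        m1, log1 = train_fold(tiny_cohort, TINY_MODEL, cfg)
        m2, log2 = train_fold(tiny_cohort, TINY_MODEL, cfg)
        assert log1 == log2
        for (p1, _), (p2, _) in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1, p2)


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def result(self, tiny_cohort):
        return cross_validate(
            tiny_cohort,
            TINY_MODEL,
            TrainConfig(epochs=3, batch_size=8, k_folds=4, seed=2),
            MixupSpec(lam=0.9, target_per_class=4, seed=2),
        )

    def test_five_fold_bookkeeping(self, result, tiny_cohort):
        assert len(result.fold_reports) == 4
        assert len(result.fold_models) == 4

    def test_summed_confusion_counts_every_sample_once(self, result, tiny_cohort):
        assert result.aggregate.confusion.sum() == len(tiny_cohort)

    def test_test_folds_are_real_samples_only(self, result, tiny_cohort):
        for _, test_idx in result.fold_indices:
            assert not any(tiny_cohort[i].synthetic for i in test_idx)

    def test_rejects_synthetic_input(self, tiny_cohort):
        from gaitstream.augment import balance_by_mixup

        augmented = balance_by_mixup(tiny_cohort, MixupSpec(target_per_class=5, seed=0))
        with pytest.raises(ValueError, match="real samples"):
            cross_validate(
                augmented, TINY_MODEL,
                TrainConfig(epochs=1, k_folds=2, seed=0),
            )

    def test_aggregate_consistency(self, result):
        manual = aggregate_reports(result.fold_reports)
        np.testing.assert_array_equal(manual.confusion, result.aggregate.confusion)
        assert manual.macro["overall_accuracy"] == result.aggregate.macro["overall_accuracy"]


def test_featurize_set_shapes(tiny_cohort):
    S, Sp, y = featurize_set(tiny_cohort)
    n = len(tiny_cohort)
    assert S.shape == (n, 20, 20, 3)
    assert Sp.shape == (n, 20, 380, 3)
    assert y.shape == (n, 4)
    np.testing.assert_array_equal(y.sum(axis=1), 1.0)
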