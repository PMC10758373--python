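"""Splits, metrics, grid enumeration, training and distillation loops."""

import numpy as np
import pandas as pd
import pytest

from sonodistill import (
    AugmentationConfig,
    ConfusionMatrix,
    DistillationConfig,
    GridSpec,
    ImageSample,
    TrainRecipe,
    build_smallnet,
    distill,
    evaluate,
    grid_search,
    report_improvement,
    split_validation,
    train,
)
from sonodistill.training import TrainingDivergedError


def make_samples(n_per_class, k=3, patients_per_class=4, size=8, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for label in range(k):
        for i in range(n_per_class):
            pid = f"C{label}P{i % patients_per_class}"
            out.append(
                ImageSample(rng.uniform(0, 1, (size, size)), label, pid, "train")
            )
    return out


class TestSplitValidation:
    def test_partition_properties(self):
        samples = make_samples(40)
        tr, val = split_validation(samples, 0.1, np.random.default_rng(0))
        assert len(tr) + len(val) == len(samples)
        assert not ({id(s) for s in tr} & {id(s) for s in val})
        assert 0 < len(val) < len(samples)

    def test_patient_disjoint(self):
        samples = make_samples(40, patients_per_class=10)
        tr, val = split_validation(samples, 0.1, np.random.default_rng(0))
        assert not ({s.patient_id for s in tr} & {s.patient_id for s in val})

    def test_ten_percent_when_patients_align(self):
        # 10 patients x 1 image per class: a 10% split is exactly 1 patient
        samples = make_samples(10, k=2, patients_per_class=10)
        tr, val = split_validation(samples, 0.1, np.random.default_rng(0))
        assert len(val) == 2 and len(tr) == 18

    def test_same_seed_same_split(self):
        samples = make_samples(30)
        tr1, val1 = split_validation(samples, 0.1, np.random.default_rng(5))
        tr2, val2 = split_validation(samples, 0.1, np.random.default_rng(5))
        assert [id(s) for s in val1] == [id(s) for s in val2]

    def test_single_patient_class_warns_and_falls_back(self):
        samples = make_samples(20, k=1, patients_per_class=1)
        with pytest.warns(UserWarning, match="fewer than two patients"):
            tr, val = split_validation(samples, 0.1, np.random.default_rng(0))
        assert len(val) == 2  # image-level stratification reaches the target

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_validation([], 0.1)


class TestConfusionMatrix:
    def test_perfect_predictions(self):
        cm = ConfusionMatrix.from_predictions([0, 1, 2], [0, 1, 2], 3)
        assert cm.accuracy() == 1.0
        assert cm.balanced_accuracy() == 1.0
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)

    def test_two_class_arithmetic(self):
        cm = ConfusionMatrix(np.array([[8, 2], [4, 6]]))
        assert cm.accuracy() == pytest.approx(0.7)
        assert cm.balanced_accuracy() == pytest.approx((0.8 + 0.6) / 2)
        assert cm.total == 20

    def test_constant_predictor_on_imbalanced_data(self):
        y_true = [0] * 30 + [1] * 5 + [2] * 5
        cm = ConfusionMatrix.from_predictions(y_true, [0] * 40, 3)
        assert cm.balanced_accuracy() == pytest.approx(1 / 3)

    def test_total_conserved_and_trace_accuracy(self, rng):
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, 4)
        assert cm.total == 100
        assert cm.counts.sum(axis=1)[1] == (y_true == 1).sum()
        assert cm.accuracy() == pytest.approx(np.trace(cm.counts) / 100)

    def test_balanced_accuracy_invariant_to_class_duplication(self, rng):
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = rng.integers(0, 2, 20)
        cm1 = ConfusionMatrix.from_predictions(y_true, y_pred, 2)
        y_dup = np.concatenate([y_true, [0] * 10])
        p_dup = np.concatenate([y_pred, y_pred[:10]])
        cm2 = ConfusionMatrix.from_predictions(y_dup, p_dup, 2)
        assert cm1.balanced_accuracy() == pytest.approx(cm2.balanced_accuracy())

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import balanced_accuracy_score, confusion_matrix

        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, 3)
        assert np.array_equal(cm.counts, confusion_matrix(y_true, y_pred, labels=[0, 1, 2]))
        assert cm.balanced_accuracy() == pytest.approx(balanced_accuracy_score(y_true, y_pred))

    def test_empty_class_excluded_with_warning(self):
        cm = ConfusionMatrix(np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]]))
        with pytest.warns(UserWarning):
            assert cm.balanced_accuracy() == pytest.approx(1.0)


class TestImprovement:
    def test_published_example(self):
        assert report_improvement(93.02, 91.29) == pytest.approx(1.73)

    def test_equal_models_zero_and_antisymmetry(self):
        assert report_improvement(90.0, 90.0) == 0.0
        assert report_improvement(88.0, 91.0) == -report_improvement(91.0, 88.0)


class TestGridSpec:
    def test_printed_grid_cardinality(self):
        grid = GridSpec()
        assert grid.cardinality == 9 * 10 * 7 * 6 * 4 == 15_120
        assert len(list(grid.enumerate())) == 15_120

    def test_sample_without_replacement_seeded(self):
        grid = GridSpec()
        s1 = grid.sample(20, np.random.default_rng(3))
        s2 = grid.sample(20, np.random.default_rng(3))
        assert s1 == s2
        assert len(set(s1)) == 20
        assert all(p in set(grid.enumerate()) for p in s1)

    def test_budget_covers_grid(self):
        small = GridSpec(lam=(0.5,), tau=(1.0, 2.0), beta=(1.0,), weight_decay=(1e-6,), lr=(0.001,))
        assert small.sample(10, np.random.default_rng(0)) == list(small.enumerate())


class TestGridSearch:
    def test_budget_one_returns_single_config(self):
        calls = []

        def objective(cfg, recipe):
            calls.append((cfg, recipe))
            return 0.5

        best_cfg, best_recipe, report = grid_search(
            GridSpec(), 1, objective, np.random.default_rng(0)
        )
        assert len(calls) == 1 and len(report) == 1
        assert best_cfg is calls[0][0]

    def test_argmax_with_first_tie_wins(self):
        small = GridSpec(lam=(0.5,), tau=(1.0, 2.0, 3.0), beta=(1.0,), weight_decay=(1e-6,), lr=(0.001,))
        scores = {1.0: 0.3, 2.0: 0.9, 3.0: 0.9}

        def objective(cfg, recipe):
            return scores[cfg.tau]

        best_cfg, _, report = grid_search(small, 10, objective, np.random.default_rng(0))
        assert best_cfg.tau == 2.0  # first of the tied maxima in enumeration order
        assert len(report) == 3

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            grid_search(GridSpec(), 0, lambda c, r: 0.0)


def _toy_separable(k=2, n=24, size=8, seed=0):
    """Linearly separable toy: class 0 bright left half, class 1 bright right."""
    rng = np.random.default_rng(seed)
    out = []
    for label in range(k):
        for i in range(n // k):
            img = np.full((size, size), 0.1) + rng.uniform(0, 0.05, (size, size))
            if label == 0:
                img[:, : size // 2] += 0.7
            else:
                img[:, size // 2 :] += 0.7
            out.append(ImageSample(np.clip(img, 0, 1), label, f"C{label}P{i}", "train"))
    return out


class TestTrainLoop:
    def test_zero_epochs_returns_initial_weights(self):
        samples = _toy_separable()
        net = build_smallnet(2, 2, rng=np.random.default_rng(0))
        before = [p.value.copy() for p in net.parameters()]
        recipe = TrainRecipe(epochs=0)
        ckpt = train(net, recipe, samples, samples[:4], None, np.random.default_rng(1))
        for p, b in zip(net.parameters(), before):
            assert np.array_equal(p.value, b)
        assert ckpt.epoch == 0

    def test_fixed_seed_reproducible(self):
        samples = _toy_separable()
        recipe = TrainRecipe(epochs=2, early_stop_patience=None)

        def run():
            net = build_smallnet(2, 2, rng=np.random.default_rng(0))
            ckpt = train(
                net, recipe, samples, samples[:6], AugmentationConfig(), np.random.default_rng(1)
            )
            return ckpt.validation_accuracy, net.parameters()[0].value.copy()

        va1, w1 = run()
        va2, w2 = run()
        assert va1 == va2
        assert np.array_equal(w1, w2)

    def test_separable_toy_reaches_perfect_accuracy(self):
        samples = _toy_separable(n=32)
        net = build_smallnet(2, 2, rng=np.random.default_rng(0))
        recipe = TrainRecipe(epochs=15, early_stop_patience=None)
        train(net, recipe, samples, samples, None, np.random.default_rng(1))
        acc, bal, _ = evaluate(net, samples)
        assert acc == 1.0 and bal == 1.0

    def test_model_selection_is_running_maximum(self):
        samples = _toy_separable(n=24)
        net = build_smallnet(2, 2, rng=np.random.default_rng(0))
        recipe = TrainRecipe(epochs=6, early_stop_patience=None)
        ckpt = train(net, recipe, samples, samples[:8], None, np.random.default_rng(1))
        assert ckpt.validation_accuracy >= ckpt.history["va"].max() - 1e-12
        # ties resolve to the earliest epoch achieving the maximum
        first_max = int(ckpt.history.loc[ckpt.history["va"].idxmax(), "epoch"])
        assert ckpt.epoch == first_max

    def test_divergence_aborts_with_diagnostic(self):
        samples = _toy_separable()
        net = build_smallnet(2, 2, rng=np.random.default_rng(0))
        net.parameters()[0].value[0, 0, 0, 0] = np.nan  # corrupt weights
        recipe = TrainRecipe(epochs=3, early_stop_patience=None)
        with pytest.raises(TrainingDivergedError, match="non-finite"):
            train(net, recipe, samples, samples[:4], None, np.random.default_rng(1))


class TestDistillLoop:
    def test_beta_zero_lambda_one_identical_to_train(self):
        samples = _toy_separable(n=24)
        recipe = TrainRecipe(epochs=3, early_stop_patience=None)
        teacher = build_smallnet(4, 2, rng=np.random.default_rng(9))
        s1 = build_smallnet(2, 2, rng=np.random.default_rng(3))
        c1 = train(s1, recipe, samples, samples[:6], None, np.random.default_rng(4))
        s2 = build_smallnet(2, 2, rng=np.random.default_rng(3))
        cfg = DistillationConfig(lam=1.0, tau=1.0, beta=0.0)
        c2 = distill(teacher, s2, cfg, recipe, samples, samples[:6], None, np.random.default_rng(4))
        assert np.allclose(c1.history["train_loss"], c2.history["train_loss"])
        for p1, p2 in zip(s1.parameters(), s2.parameters()):
            assert np.array_equal(p1.value, p2.value)

    def test_feature_distillation_runs_and_selects(self):
        samples = _toy_separable(n=24, size=12)
        recipe = TrainRecipe(epochs=2, early_stop_patience=None)
        teacher = build_smallnet(4, 2, rng=np.random.default_rng(9))
        student = build_smallnet(2, 2, rng=np.random.default_rng(3))
        cfg = DistillationConfig(lam=0.5, tau=2.0, beta=1.0, n_tiers=3)
        ckpt = distill(
            teacher, student, cfg, recipe, samples, samples[:6], None, np.random.default_rng(4)
        )
        assert len(ckpt.history) == 2
        assert ckpt.projection_states is not None and len(ckpt.projection_states) == 3
        assert np.isfinite(ckpt.history["train_loss"]).all()

    def test_teacher_weights_untouched_by_distillation(self):
        samples = _toy_separable(n=16)
        recipe = TrainRecipe(epochs=1, early_stop_patience=None)
        teacher = build_smallnet(4, 2, rng=np.random.default_rng(9))
        before = [p.value.copy() for p in teacher.parameters()]
        student = build_smallnet(2, 2, rng=np.random.default_rng(3))
        cfg = DistillationConfig(lam=0.5, tau=2.0, beta=5.0, n_tiers=2)
        distill(teacher, student, cfg, recipe, samples, samples[:4], None, np.random.default_rng(4))
        for p, b in zip(teacher.parameters(), before):
            assert np.array_equal(p.value, b)


def test_evaluate_channel_adaptation():
    """Grayscale samples evaluate against a 3-channel network by
    replication."""
    from sonodistill import build_vgg16_head

    samples = _toy_separable(n=4, size=32, k=2)
    net = build_vgg16_head(2, rng=np.random.default_rng(0))
    acc, bal, cm = evaluate(net, samples)
    assert cm.total == 4


def test_external_teacher_adapter_distills():
    """A teacher wrapped in the ExternalTeacher adapter drives the same
    distillation loop as a native network."""
    from sonodistill import ExternalTeacher, get_feature_taps

    samples = _toy_separable(n=16, size=12)
    native = build_smallnet(4, 2, rng=np.random.default_rng(9))
    wrapped = ExternalTeacher(
        forward_fn=lambda x, depths: native.forward(x, tap_depths=depths)
        if depths
        else native.forward(x),
        rectified_channels=[c for _, c in native.rectified_convs],
        num_classes=2,
        input_channels=1,
    )
    assert [t.depth for t in get_feature_taps(wrapped, 3)] == [1, 3, 5]
    student = build_smallnet(2, 2, rng=np.random.default_rng(3))
    cfg = DistillationConfig(lam=0.5, tau=2.0, beta=1.0, n_tiers=3)
    recipe = TrainRecipe(epochs=1, early_stop_patience=None)
    ckpt = distill(wrapped, student, cfg, recipe, samples, samples[:4], None, np.random.default_rng(4))
    assert np.isfinite(ckpt.history["train_loss"]).all()
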