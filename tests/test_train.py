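"""Training protocol, stratified splitting/folding, MPCE, comparison."""

import numpy as np
import pytest

from sargnet.dataset import NoDataError, class_counts
from sargnet.nn import build
from sargnet.simulate import bayes_accuracy, default_config, generate
from sargnet.specs import erisnet_spec, fcn_spec, mlp_spec
from sargnet.train import (
    PixelClassifier,
    TrainingConfig,
    compare_models,
    evaluate_accuracy,
    kfold_cv,
    mpce,
    split_train_test,
    stratified_folds,
    train,
)

from conftest import labeled_zeros

FAST = TrainingConfig(epochs=5, batch_size=100, seed=1)


class TestSplit:
    def test_study_sized_split_rounds_toward_training(self, study_shaped_dataset):
        train_set, test_set = split_train_test(study_shaped_dataset, 0.5, seed=1)
        assert (len(train_set), len(test_set)) == (2258, 2257)
        # per class: ceil(0.5·2306)=1153 and ceil(0.5·2209)=1105 go to train
        assert class_counts(train_set) == (1153, 1105)
        assert class_counts(test_set) == (1153, 1104)

    def test_same_seed_identical_partition(self, small_dataset):
        a = split_train_test(small_dataset, 0.5, seed=4)
        b = split_train_test(small_dataset, 0.5, seed=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.features(), y.features())

    def test_union_conserves_class_counts_and_rows(self, small_dataset):
        train_set, test_set = split_train_test(small_dataset, 0.3, seed=2)
        assert len(train_set) + len(test_set) == len(small_dataset)
        n1, n0 = class_counts(small_dataset)
        t1, t0 = class_counts(train_set)
        v1, v0 = class_counts(test_set)
        assert (t1 + v1, t0 + v0) == (n1, n0)
        combined = np.vstack([train_set.features(), test_set.features()])
        assert {tuple(r) for r in combined} == {tuple(r) for r in small_dataset.features()}

    def test_tiny_class_cannot_be_stratified(self):
        with pytest.raises(ValueError, match="stratify"):
            split_train_test(labeled_zeros(1, 10), 0.5, seed=1)


class TestMpce:
    def test_hand_examples(self):
        assert mpce((10, 10), (10, 10)) == 1.0
        assert mpce((8, 9), (10, 10)) == pytest.approx(0.85)

    def test_matches_loop_oracle_on_random_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = rng.integers(2, 11)
            totals = rng.integers(1, 100, k)
            corrects = rng.integers(0, totals + 1)
            expected = sum(e / c for e, c in zip(corrects, totals)) / k
            assert mpce(corrects, totals) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "e,c", [((1,), (0,)), ((5, 1), (4, 2)), ((1, 2), (3,)), ((), ())]
    )
    def test_domain_errors(self, e, c):
        with pytest.raises(ValueError):
            mpce(e, c)


class TestFolds:
    def test_folds_partition_the_dataset(self, small_dataset):
        folds = stratified_folds(small_dataset.labels, k=5, seed=3)
        joined = np.concatenate(folds)
        assert len(joined) == len(set(joined)) == len(small_dataset)

    def test_study_sized_folds_are_903_each(self, study_shaped_dataset):
        folds = stratified_folds(study_shaped_dataset.labels, k=5, seed=1)
        assert [len(f) for f in folds] == [903] * 5

    def test_class_proportions_within_one_pixel(self, small_dataset):
        labels = small_dataset.labels
        global_ratio = labels.mean()
        for fold in stratified_folds(labels, k=5, seed=3):
            n_with = labels[fold].sum()
            assert abs(n_with - global_ratio * len(fold)) <= 1

    def test_k_larger_than_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(labeled_zeros(3, 50).labels, k=5, seed=1)


class TestTraining:
    def test_two_runs_same_seed_identical_curves(self, small_dataset):
        train_set, test_set = split_train_test(small_dataset, 0.5, seed=1)
        curves = []
        for _ in range(2):
            model = build(mlp_spec(), seed=1)
            _, c = train(model, train_set, test_set, FAST)
            curves.append(c)
        assert curves[0].train_accuracy == curves[1].train_accuracy
        assert curves[0].test_accuracy == curves[1].test_accuracy

    def test_curves_have_one_entry_per_epoch(self, small_dataset):
        train_set, test_set = split_train_test(small_dataset, 0.5, seed=1)
        _, c = train(build(mlp_spec(), seed=1), train_set, test_set, FAST)
        assert len(c.train_accuracy) == len(c.test_accuracy) == FAST.epochs

    @pytest.mark.parametrize(
        "spec_factory,epochs", [(mlp_spec, 30), (fcn_spec, 60), (erisnet_spec, 120)]
    )
    def test_separable_data_is_learned_perfectly(self, separable_dataset, spec_factory, epochs):
        """All architectures reach training accuracy 1.0 on noise-free data."""
        train_set, test_set = split_train_test(separable_dataset, 0.5, seed=1)
        config = TrainingConfig(epochs=epochs, batch_size=100, seed=1)
        _, curves = train(build(spec_factory(), seed=1), train_set, test_set, config)
        assert max(curves.train_accuracy) == 1.0

    def test_test_accuracy_near_but_not_above_bayes_ceiling(self, small_config):
        """A trained classifier approaches the analytic optimum of the
        generative mixture and cannot meaningfully exceed it."""
        config = small_config.with_(n_per_class=2000, seed=2)
        ds = generate(config)
        train_set, test_set = split_train_test(ds, 0.5, seed=2)
        model = build(mlp_spec(), seed=2)
        _, curves = train(model, train_set, test_set,
                          TrainingConfig(epochs=30, batch_size=100, seed=2))
        ceiling = bayes_accuracy(config)
        se = np.sqrt(ceiling * (1 - ceiling) / len(test_set))
        accuracy = evaluate_accuracy(model, test_set)
        assert accuracy <= ceiling + 3 * se
        assert accuracy >= ceiling - 3 * se  # and it actually learns

    def test_nonfinite_loss_aborts_with_location(self, small_dataset):
        train_set, test_set = split_train_test(small_dataset, 0.5, seed=1)
        model = build(mlp_spec(), seed=1)
        model.params()[0].value[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="epoch 1, batch 1"):
            train(model, train_set, test_set, FAST)

    def test_empty_test_set_raises(self, small_dataset):
        model = build(mlp_spec(), seed=1)
        with pytest.raises(NoDataError):
            evaluate_accuracy(model, small_dataset.subset([]))

    def test_zeroed_head_predicts_one_class_giving_half_on_balanced_data(self, small_dataset):
        model = build(mlp_spec(), seed=1)
        head = [layer for layer in model.layers if layer.params()][-1]
        for param in head.params():
            param.value[...] = 0.0
        assert evaluate_accuracy(model, small_dataset) == 0.5


class TestKFold:
    def test_two_fold_on_separable_data_is_perfect(self, separable_dataset):
        config = TrainingConfig(epochs=40, batch_size=100, seed=1)
        cv = kfold_cv(mlp_spec(), separable_dataset, k=2, config=config)
        assert cv.mpce == 1.0
        assert cv.per_fold_accuracy == (1.0, 1.0)

    def test_result_bookkeeping(self, small_dataset):
        cv = kfold_cv(mlp_spec(), small_dataset, k=3, config=FAST)
        assert cv.k == 3 and len(cv.curves) == 3
        assert sum(cv.per_fold_total) == len(small_dataset)
        assert cv.mpce == pytest.approx(np.mean(cv.per_fold_accuracy))
        for e, c, a in zip(cv.per_fold_correct, cv.per_fold_total, cv.per_fold_accuracy):
            assert a == e / c


class TestCompare:
    def test_single_model_request(self, small_dataset):
        result = compare_models(small_dataset, FAST, models=("mlp",), protocol="split")
        assert len(result.rows) == 1
        assert result.rows[0].model == "mlp"

    def test_deltas_recompute_from_table(self, separable_dataset):
        config = TrainingConfig(epochs=3, batch_size=100, seed=1)
        result = compare_models(
            separable_dataset, config, models=("mlp", "fcn"), protocol="split"
        )
        deltas = result.deltas()
        assert deltas[("mlp", "fcn")] == pytest.approx(
            result.accuracy("mlp") - result.accuracy("fcn")
        )
        assert deltas[("mlp", "fcn")] == -deltas[("fcn", "mlp")]

    def test_study_protocol_crossvalidates_erisnet(self, separable_dataset):
        config = TrainingConfig(epochs=2, batch_size=100, seed=1)
        result = compare_models(
            separable_dataset, config, models=("mlp", "erisnet"), protocol="study", k=2
        )
        protocols = {r.model: r.protocol for r in result.rows}
        assert protocols["mlp"].endswith("split")
        assert protocols["erisnet"] == "2-fold"


class TestModelObjects:
    def test_fit_returns_result_with_summary(self, small_dataset):
        train_set, test_set = split_train_test(small_dataset, 0.5, seed=1)
        clf = PixelClassifier(mlp_spec(), FAST)
        result = clf.fit(train_set, test_set)
        text = result.summary()
        assert "mlp" in text and "509,502" in text
        assert f"{result.test_accuracy:.4f}" in text

    def test_result_predictions_consistent_with_evaluator(self, small_dataset):
        train_set, test_set = split_train_test(small_dataset, 0.5, seed=1)
        result = PixelClassifier(mlp_spec(), FAST).fit(train_set, test_set)
        accuracy = np.mean(result.predict(test_set) == test_set.labels)
        assert accuracy == pytest.approx(result.accuracy(test_set))
        proba = result.predict_proba(test_set)
        np.testing.assert_array_equal(
            result.predict(test_set), (proba[:, 1] > 0.5).astype(int)
        )

    def test_standardized_inputs_thread_through_prediction(self, small_dataset):
        train_set, test_set = split_train_test(small_dataset, 0.5, seed=1)
        clf = PixelClassifier(mlp_spec(), FAST.with_(standardize_inputs=True))
        result = clf.fit(train_set, test_set)
        assert result.model.input_mean is not None
        proba = result.predict_proba(test_set)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
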