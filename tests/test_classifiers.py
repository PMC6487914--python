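"""Balancing, CV plans, leakage-safe normalization and base classifiers."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from msel.classifiers import (
    balance_classes,
    apply_normalizer,
    cross_validate,
    evaluate,
    fit_lr_lasso,
    fit_normalizer,
    fit_rf,
    make_cv_plan,
    predict,
)


def _ids_labels(n_pos, n_neg):
    ids = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    labels = {i: 1 if i.startswith("p") else 0 for i in ids}
    return ids, labels


class TestBalance:
    def test_min_rule(self):
        ids, labels = _ids_labels(10, 4)
        out = balance_classes(ids, labels, seed=0)
        assert sum(labels[i] for i in out) == 4 and len(out) == 8

    def test_already_balanced_identity_up_to_order(self):
        ids, labels = _ids_labels(5, 5)
        assert sorted(balance_classes(ids, labels, seed=3)) == sorted(ids)

    def test_large_imbalanced_pool(self):
        # majority undersampled to the minority size on a cohort-scale pool
        ids, labels = _ids_labels(687, 291)
        out = balance_classes(ids, labels, seed=1)
        assert sum(labels[i] for i in out) == 291 and len(out) == 582

    def test_deterministic_and_seed_sensitive(self):
        ids, labels = _ids_labels(30, 10)
        a = balance_classes(ids, labels, seed=7)
        assert a == balance_classes(ids, labels, seed=7)
        assert a != balance_classes(ids, labels, seed=8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_classes(["a", "b"], {"a": 1, "b": 1}, seed=0)

    def test_oversample(self):
        ids, labels = _ids_labels(10, 4)
        out = balance_classes(ids, labels, seed=0, method="oversample")
        assert len(out) == 20 and sum(labels[i] for i in out) == 10


class TestCVPlan:
    def test_exact_division_one_per_class_per_fold(self):
        ids, labels = _ids_labels(10, 10)
        plan = make_cv_plan(ids, labels, n_folds=10, n_repeats=2, seed=0)
        for rep in plan.folds:
            for _, va in rep:
                y = [labels[i] for i in va]
                assert sum(y) == 1 and len(y) == 2

    def test_stratification_within_one(self):
        ids, labels = _ids_labels(15, 15)
        plan = make_cv_plan(ids, labels, n_folds=4, n_repeats=3, seed=5)
        for rep in plan.folds:
            for _, va in rep:
                y = [labels[i] for i in va]
                assert abs(sum(y) - (len(y) - sum(y))) <= 1

    def test_folds_partition_the_balanced_pool(self):
        ids, labels = _ids_labels(12, 20)
        plan = make_cv_plan(ids, labels, n_folds=4, n_repeats=2, seed=1)
        for rep in plan.folds:
            val_ids = [i for _, va in rep for i in va]
            assert len(val_ids) == len(set(val_ids)) == 24  # 2 * min class size

    def test_same_seed_identical(self):
        ids, labels = _ids_labels(10, 14)
        assert make_cv_plan(ids, labels, 5, 2, seed=9).folds == make_cv_plan(ids, labels, 5, 2, seed=9).folds

    def test_too_many_folds_rejected(self):
        ids, labels = _ids_labels(4, 4)
        with pytest.raises(ValueError):
            make_cv_plan(ids, labels, n_folds=10, n_repeats=1, seed=0)


class TestNormalizer:
    def test_hand_arithmetic(self):
        params = fit_normalizer(np.array([[0.0], [2.0]]))
        assert params.mean[0] == 1.0 and params.std[0] == 1.0
        assert apply_normalizer(params, np.array([[3.0]]))[0, 0] == 2.0

    def test_constant_column_guarded(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        params = fit_normalizer(X)
        assert params.constant_mask.tolist() == [True, False]
        out = apply_normalizer(params, X)
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_train_columns_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).normal(3, 5, size=(40, 6))
        out = apply_normalizer(fit_normalizer(X), X)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_no_leakage_validation_uses_training_params(self):
        # Rescaling validation rows must shift their transformed values when
        # (and only when) training params are used; fitting on the validation
        # rows would incorrectly absorb the corruption.
        rng = np.random.default_rng(1)
        Xtr, Xva = rng.normal(size=(30, 3)), rng.normal(size=(10, 3))
        params = fit_normalizer(Xtr)
        correct = apply_normalizer(params, 10 * Xva)
        assert not np.allclose(correct, apply_normalizer(params, Xva))
        leaky = apply_normalizer(fit_normalizer(10 * Xva), 10 * Xva)
        np.testing.assert_allclose(leaky, apply_normalizer(fit_normalizer(Xva), Xva), atol=1e-9)


def _toy(n=120, p=5, effect=2.0, seed=0, noisy=True):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, p))
    X[:, 0] += effect * y
    if noisy:
        X[:, 0] += rng.standard_normal(n)  # keep classes overlapping
    return X, y


class TestLrLasso:
    def test_full_shrinkage_gives_prevalence_response(self):
        X, y = _toy()
        m = fit_lr_lasso(X, y, lambda_grid=[1e6])
        assert m.support.size == 0
        np.testing.assert_allclose(m.predict_soft(X), 0.5)

    def test_tiny_penalty_matches_unpenalized_fit(self):
        # non-separable toy; reference is an unpenalized logistic solver
        X, y = _toy(effect=1.0)
        m = fit_lr_lasso(X, y, lambda_grid=[1e-6])
        norm = m.normalization
        ref = LogisticRegression(C=np.inf, max_iter=5000).fit(apply_normalizer(norm, X), y)
        np.testing.assert_allclose(m.estimator.coef_[0], ref.coef_[0], atol=2e-2)

    def test_recovers_informative_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            y = np.repeat([0, 1], n // 2)
            X = rng.standard_normal((n, 51))
            X[:, 0] += 2.0 * y  # one informative feature among 50 noise
            m = fit_lr_lasso(X, y, cv_seed=seed)
            hits += 0 in m.support
        assert hits >= 18

    def test_support_consistency(self):
        X, y = _toy()
        m = fit_lr_lasso(X, y, cv_seed=1)
        assert set(m.support) == set(np.flatnonzero(m.estimator.coef_[0]))


class TestRandomForest:
    def test_pure_signal_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 3))
        y = (X[:, 1] > 0).astype(int)
        m = fit_rf(X, y, seed=0, n_estimators=50)
        hard, _ = predict(m, X)
        assert (hard == y).mean() == 1.0

    def test_deterministic_given_seed(self):
        X, y = _toy(seed=2)
        a = fit_rf(X, y, seed=5, n_estimators=50).predict_soft(X)
        b = fit_rf(X, y, seed=5, n_estimators=50).predict_soft(X)
        np.testing.assert_array_equal(a, b)

    def test_permuted_labels_near_chance(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        n = 100
        ids = [f"s{i}" for i in range(n)]
        X = pd.DataFrame(rng.standard_normal((n, 5)), index=ids)
        labels = {i: int(v) for i, v in zip(ids, rng.permutation(np.repeat([0, 1], n // 2)))}
        plan = make_cv_plan(ids, labels, n_folds=5, n_repeats=2, seed=0)
        res = cross_validate("rf", X, labels, plan, seed=0, n_estimators=50)
        assert abs(res["accuracy"].mean() - 0.5) < 0.12


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        m = evaluate(y, y.astype(float), y)
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_all_positive_on_imbalanced_test(self):
        # 87 cases / 46 controls, predict everyone positive
        y = np.array([1] * 87 + [0] * 46)
        preds = np.ones_like(y)
        m = evaluate(preds, preds.astype(float), y)
        assert m.accuracy == pytest.approx(87 / 133, abs=1e-12)
        assert m.f1 == pytest.approx(2 * 87 / (2 * 87 + 46), abs=1e-12)

    def test_inverted_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = evaluate(1 - y, (1 - y).astype(float), y)
        assert m.accuracy == 0.0 and m.f1 == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [0.6, 0.4], [1])

    def test_repeated_cv_report_matches_per_fold_table(self):
        import pandas as pd

        X, y = _toy(n=60, seed=4)
        ids = [f"s{i}" for i in range(60)]
        labels = dict(zip(ids, (int(v) for v in y)))
        plan = make_cv_plan(ids, labels, n_folds=5, n_repeats=2, seed=0)
        res = cross_validate("rf", pd.DataFrame(X, index=ids), labels, plan, seed=0, n_estimators=30)
        assert len(res) == 10
        assert res["accuracy"].mean() == pytest.approx(np.mean(res["accuracy"].to_numpy()))
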