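"""LASSO / SG-LASSO solver correctness and the CDL/IDL selection pipelines."""

import numpy as np
import pytest
from dataclasses import replace

from msel.cohort import complete_design_matrix, split_train_test
from msel.featsel import (
    WeightVector,
    complete_dataset_learning,
    incomplete_dataset_learning,
    lambda_max_lasso,
    lasso_objective,
    rank_features,
    sg_lasso_objective,
    solve_lasso,
    solve_sg_lasso,
)
from msel.simulate import generate_cohort, heterogeneous_config


def _instance(seed, n=40, p=12, k=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[rng.choice(p, k, replace=False)] = rng.normal(0, 2, k)
    y = X @ beta + rng.standard_normal(n)
    return X, y - y.mean()


class TestLasso:
    def test_full_shrinkage_at_lambda_max(self):
        X, y = _instance(0)
        lam = lambda_max_lasso(X, y)
        assert not solve_lasso(X, y, lam).beta.any()
        assert solve_lasso(X, y, lam * 0.99).beta.any()

    def test_zero_penalty_equals_least_squares(self):
        X, y = _instance(1, n=60, p=8)
        wv = solve_lasso(X, y, 0.0, tol=1e-12)
        ref, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(wv.beta, ref, atol=1e-6)

    def test_orthonormal_closed_form(self):
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.standard_normal((30, 6)))
        y = rng.standard_normal(30)
        lam = 0.3
        wv = solve_lasso(Q, y, lam, tol=1e-14)
        z = Q.T @ y
        expected = np.sign(z) * np.maximum(np.abs(z) - lam, 0)
        np.testing.assert_allclose(wv.beta, expected, atol=1e-10)

    def test_kkt_residual_small(self):
        X, y = _instance(3)
        wv = solve_lasso(X, y, 1.5, tol=1e-12)
        assert wv.converged and wv.kkt_residual < 1e-5

    def test_matches_reference_lasso_implementation(self):
        # independent oracle: scikit-learn's coordinate descent (note its
        # objective divides the quadratic term by n, so alpha = lam / n)
        from sklearn.linear_model import Lasso

        for seed in range(5):
            X, y = _instance(seed, n=50, p=15)
            lam = 0.3 * lambda_max_lasso(X, y)
            ours = solve_lasso(X, y, lam, tol=1e-12)
            ref = Lasso(alpha=lam / len(y), fit_intercept=False, tol=1e-12).fit(X, y)
            np.testing.assert_allclose(ours.beta, ref.coef_, atol=1e-6)

    def test_path_support_monotone_on_orthogonal_design(self):
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.standard_normal((40, 10)))
        y = rng.standard_normal(40)
        sizes = [solve_lasso(Q, y, lam).support.size for lam in np.linspace(0.01, 1.0, 12)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_negative_penalty_rejected(self):
        X, y = _instance(0)
        with pytest.raises(ValueError):
            solve_lasso(X, y, -1.0)


class TestSGLasso:
    def test_reduces_to_lasso_at_zero_group_penalty(self):
        X, y = _instance(5, n=50, p=10)
        groups = np.array([0] * 4 + [1] * 6)
        lam = 0.2 * lambda_max_lasso(X, y)
        a = solve_sg_lasso(X, y, lam, 0.0, groups, tol=1e-12)
        b = solve_lasso(X, y, lam, tol=1e-12)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-5)

    def test_singleton_groups_pure_l2_equals_lasso(self):
        # with |group| = 1, sqrt(p_i)*||b_i||_2 = |b_i|, so SG(0, lam) = LASSO(lam)
        X, y = _instance(6, n=40, p=8)
        groups = np.arange(8)
        lam = 0.25 * lambda_max_lasso(X, y)
        a = solve_sg_lasso(X, y, 0.0, lam, groups, tol=1e-12)
        b = solve_lasso(X, y, lam, tol=1e-12)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-5)

    def test_group_shrinkage_threshold(self):
        X, y = _instance(7, n=30, p=5)
        groups = np.zeros(5, dtype=int)
        lam2 = np.linalg.norm(X.T @ y) / np.sqrt(5) + 1e-6
        assert not solve_sg_lasso(X, y, 0.0, lam2, groups).beta.any()

    def test_large_group_penalty_zeroes_noise_group(self):
        rng = np.random.default_rng(8)
        n = 80
        X = rng.standard_normal((n, 10))
        X = (X - X.mean(0)) / X.std(0)
        groups = np.array([0] * 5 + [1] * 5)
        beta = np.zeros(10)
        beta[:3] = 2.0  # signal confined to group 0
        y = X @ beta + 0.5 * rng.standard_normal(n)
        y = y - y.mean()
        wv = solve_sg_lasso(X, y, 0.5, 6.0, groups)
        assert not wv.beta[5:].any()
        assert wv.beta[:5].any()

    def test_objective_not_worse_than_smoothed_oracle(self):
        from scipy.optimize import minimize

        X, y = _instance(9, n=30, p=8)
        groups = np.array([0] * 3 + [1] * 5)
        lam1, lam2 = 0.8, 0.6
        wv = solve_sg_lasso(X, y, lam1, lam2, groups, tol=1e-12)
        eps = 1e-12

        def smooth(b):
            r = y - X @ b
            val = 0.5 * r @ r + lam1 * np.sqrt(b**2 + eps).sum()
            for g in (0, 1):
                bg = b[groups == g]
                val += lam2 * np.sqrt(len(bg)) * np.sqrt(bg @ bg + eps)
            return val

        res = minimize(smooth, np.zeros(8), method="L-BFGS-B", options={"maxiter": 5000})
        ours = sg_lasso_objective(X, y, wv.beta, lam1, lam2, groups)
        assert ours <= res.fun + 1e-6


class TestRankFeatures:
    def _wv(self, beta, groups=None):
        beta = np.asarray(beta, dtype=float)
        groups = np.zeros(len(beta), dtype=int) if groups is None else np.asarray(groups)
        return WeightVector(beta=beta, group_index=groups, lambdas={"lam": 1.0},
                            feature_names=[f"f{i}" for i in range(len(beta))])

    def test_absolute_value_ordering(self):
        out = rank_features(self._wv([0.5, -0.9, 0.0]), k=2)
        assert out["feature"].tolist() == ["f1", "f0"]

    def test_all_zero_gives_empty(self):
        assert rank_features(self._wv([0.0, 0.0]), k=3).empty

    def test_k_larger_than_support_returns_all(self):
        out = rank_features(self._wv([1.0, 0.0, -2.0]), k=10)
        assert len(out) == 2 and out["rank"].tolist() == [1, 2]

    def test_tie_break_by_group_then_column(self):
        out = rank_features(self._wv([0.5, -0.5, 0.5], groups=[1, 0, 0]), k=3)
        assert out["feature"].tolist() == ["f1", "f2", "f0"]


@pytest.fixture(scope="module")
def small_het():
    cfg = replace(heterogeneous_config(), n_subjects=250)
    cohort, truth = generate_cohort(replace(cfg, seed=42))
    return cohort, truth, split_train_test(cohort)


class TestPipelines:
    def test_cdl_selects_overlapping_support(self, small_het):
        cohort, truth, part = small_het
        wv, metrics = complete_dataset_learning(cohort, part, n_lambda=4, seed=0)
        assert metrics["p"] == 55
        truth_cols = set(truth.informative_columns(cohort.spec).tolist())
        assert truth_cols & set(wv.support.tolist())

    def test_idl_uses_more_rows_than_cdl_and_overlaps_truth(self, small_het):
        cohort, truth, part = small_het
        sel, metrics = incomplete_dataset_learning(cohort, part, n_lambda=4, seed=0)
        n_c = len(part.test_ids)
        for src, shape in metrics["stage1_shapes"].items():
            assert shape[0] >= n_c  # every stage-1 pool at least as large
        assert any(shape[0] > n_c for shape in metrics["stage1_shapes"].values())
        truth_cols = set(truth.informative_columns(cohort.spec).tolist())
        assert truth_cols & set(sel.stage1_columns.tolist())
        assert set(sel.final_columns.tolist()) <= set(sel.stage1_columns.tolist())

    def test_signal_confined_to_one_source(self):
        cfg = replace(
            heterogeneous_config(),
            n_subjects=250,
            informative_counts={"tapping": 0, "walking": 0, "voice": 5, "memory": 0},
            heterogeneity=1.0,
            seed=11,
        )
        cohort, truth = generate_cohort(cfg)
        part = split_train_test(cohort)
        sel, _ = incomplete_dataset_learning(cohort, part, n_lambda=4, seed=0)
        _, _, gidx = complete_design_matrix(cohort, part)
        src_of = [cohort.spec.names[int(g)] for g in gidx]
        picked = [src_of[c] for c in sel.stage1_columns]
        assert picked.count("voice") >= len(picked) / 2
        final_srcs = [src_of[c] for c in sel.final_columns]
        assert not final_srcs or final_srcs.count("voice") >= len(final_srcs) / 2
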