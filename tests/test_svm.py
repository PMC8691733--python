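"""Selection filter and the class-weighted squared-hinge SVM, checked
against a general-purpose convex solve of the identical objective."""

import numpy as np
import pytest
from scipy import stats

import mcisvm as m
from mcisvm.svm import _sample_costs


def _random_instance(seed, n=10, p=5, imbalance=False):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if imbalance:
        y = np.array([1] * (n - n // 3) + [-1] * (n // 3))
    else:
        y = np.where(rng.random(n) < 0.5, 1, -1)
        if len(np.unique(y)) == 1:
            y[0] = -y[0]
    return X, y


class TestTtestFilter:
    def test_constant_column_excluded(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        X[:, 1] = 5.0
        y = np.array([1] * 12 + [-1] * 8)
        mask = m.ttest_filter(X, y, np.arange(20), alpha=0.5)
        assert not mask.keep[1]
        assert np.isnan(mask.t_stat[1])

    def test_between_class_constant_column_kept(self):
        # zero within-class variance, different means: p = 0
        y = np.array([1] * 5 + [-1] * 5)
        X = np.where(y == 1, 1.0, 2.0)[:, None].astype(float)
        mask = m.ttest_filter(X, y, np.arange(10), alpha=0.01)
        assert mask.keep[0] and mask.p_value[0] == 0.0

    def test_planted_column_always_kept(self):
        """Standardized mean difference 5 at n = 54: detected every time."""
        y = np.array([1] * 40 + [-1] * 14)
        kept = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((54, 1))
            X[y == -1, 0] += 5.0
            kept += m.ttest_filter(X, y, np.arange(54)).keep[0]
        assert kept == 100

    def test_null_kept_fraction_near_alpha(self):
        """Pure noise: kept fraction compatible with alpha = 0.01."""
        y = np.array([1] * 14 + [-1] * 7)
        total = kept = 0
        for seed in range(60):
            X = np.random.default_rng(1000 + seed).standard_normal((21, 400))
            mask = m.ttest_filter(X, y, np.arange(21))
            kept += mask.n_selected
            total += 400
        rate = kept / total
        tol = 4 * np.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) < tol

    def test_matches_scipy_student_t(self):
        X, y = _random_instance(3, n=24, p=30)
        mask = m.ttest_filter(X, y, np.arange(24))
        ref = stats.ttest_ind(X[y == 1], X[y == -1], axis=0, equal_var=True)
        np.testing.assert_allclose(mask.t_stat, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(mask.p_value, ref.pvalue, rtol=1e-10)

    def test_welch_variant_matches_scipy(self):
        X, y = _random_instance(4, n=24, p=10)
        mask = m.ttest_filter(X, y, np.arange(24), variant="welch")
        ref = stats.ttest_ind(X[y == 1], X[y == -1], axis=0, equal_var=False)
        np.testing.assert_allclose(mask.p_value, ref.pvalue, rtol=1e-10)

    def test_mask_ignores_non_training_rows(self):
        X, y = _random_instance(5, n=20, p=8)
        train = np.arange(15)
        mask1 = m.ttest_filter(X, y, train)
        X2 = X.copy()
        X2[16:] = 1e6
        mask2 = m.ttest_filter(X2, y, train)
        np.testing.assert_array_equal(mask1.keep, mask2.keep)
        np.testing.assert_array_equal(mask1.p_value, mask2.p_value)

    def test_small_class_raises(self):
        X = np.zeros((5, 2))
        y = np.array([1, 1, 1, 1, -1])
        with pytest.raises(ValueError):
            m.ttest_filter(X, y, np.arange(5))


class TestClassCosts:
    def test_study_imbalance(self):
        y = np.array([1] * 40 + [-1] * 14)
        cost = m.class_cost_from_counts(y)
        assert cost[1] == pytest.approx(54 / 80)
        assert cost[-1] == pytest.approx(54 / 28)
        assert cost[-1] > cost[1]  # minority (decline) penalized more

    def test_balance_gives_unit_costs(self):
        cost = m.class_cost_from_counts(np.array([1] * 10 + [-1] * 10))
        assert cost == {1: 1.0, -1: 1.0}

    def test_scale_invariance(self):
        a = m.class_cost_from_counts(np.array([1] * 10 + [-1] * 4))
        b = m.class_cost_from_counts(np.array([1] * 20 + [-1] * 8))
        assert a == b

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            m.class_cost_from_counts(np.array([1, 1, 1]))


class TestSquaredHingeSVM:
    def test_toy_1d_separable(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        model = m.train_weighted_linear_svm(X, y, C=100.0, class_cost={1: 1.0, -1: 1.0})
        oracle = m.qp_oracle(X, y, C=100.0, class_cost={1: 1.0, -1: 1.0})
        assert model.w[0] == pytest.approx(1.0, abs=1e-2)
        assert model.b == pytest.approx(0.0, abs=1e-6)
        assert model.objective == pytest.approx(oracle.objective, abs=1e-6)
        lab_neg, _ = m.predict(model, np.array([-1.0]))
        lab_pos, _ = m.predict(model, np.array([1.0]))
        lab_mid, _ = m.predict(model, np.array([0.2]))
        assert (lab_neg, lab_pos, lab_mid) == (-1, 1, 1)

    @pytest.mark.parametrize("C", [0.1, 1.0, 10.0])
    def test_agrees_with_general_purpose_solver(self, C):
        """Newton solution matches the quasi-Newton oracle within 1e-6 in
        objective on random weighted instances."""
        for seed in range(20):
            X, y = _random_instance(seed, n=10, p=5, imbalance=(seed % 2 == 0))
            cost = m.class_cost_from_counts(y)
            model = m.train_weighted_linear_svm(X, y, C, cost)
            oracle = m.qp_oracle(X, y, C, cost)
            c = _sample_costs(y, C, cost)
            assert m.svm_objective(model.w, model.b, X, y, c) <= oracle.objective + 1e-6
            assert abs(model.objective - oracle.objective) < 1e-6

    def test_objective_field_is_true_objective(self):
        X, y = _random_instance(42, n=12, p=4)
        cost = m.class_cost_from_counts(y)
        model = m.train_weighted_linear_svm(X, y, 2.0, cost)
        c = _sample_costs(y, 2.0, cost)
        assert model.objective == pytest.approx(
            m.svm_objective(model.w, model.b, X, y, c), rel=1e-10
        )

    def test_integer_cost_equals_sample_duplication(self):
        """Cost k on a class is algebraically identical to duplicating its
        samples k times at cost 1."""
        X, y = _random_instance(7, n=9, p=3, imbalance=True)
        k = 3
        weighted = m.train_weighted_linear_svm(X, y, 1.0, {1: 1.0, -1: float(k)})
        dup_rows = np.concatenate([np.flatnonzero(y == 1)] + [np.flatnonzero(y == -1)] * k)
        dup = m.train_weighted_linear_svm(X[dup_rows], y[dup_rows], 1.0, {1: 1.0, -1: 1.0})
        np.testing.assert_allclose(weighted.w, dup.w, atol=1e-6)
        assert weighted.b == pytest.approx(dup.b, abs=1e-6)
        assert weighted.objective == pytest.approx(dup.objective, abs=1e-6)

    def test_label_swap_negates_solution(self):
        X, y = _random_instance(8, n=10, p=4, imbalance=True)
        cost = m.class_cost_from_counts(y)
        a = m.train_weighted_linear_svm(X, y, 1.0, cost)
        swapped_cost = {1: cost[-1], -1: cost[1]}
        b = m.train_weighted_linear_svm(X, -y, 1.0, swapped_cost)
        np.testing.assert_allclose(a.w, -b.w, atol=1e-6)
        assert a.b == pytest.approx(-b.b, abs=1e-6)

    def test_separable_large_C_drives_loss_to_zero(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([-1, -1, 1, 1])
        model = m.train_weighted_linear_svm(X, y, C=1e6, class_cost={1: 1.0, -1: 1.0})
        c = _sample_costs(y, 1e6, {1: 1.0, -1: 1.0})
        loss = m.svm_objective(model.w, model.b, X, y, c) - 0.5 * model.w @ model.w
        assert loss < 1e-3

    def test_unsquared_hinge_option_matches_reference(self):
        """The sensitivity-analysis hinge mode reaches at least the
        objective of an independent reference solve of the same problem."""
        from sklearn.svm import SVC

        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((12, 4))
            y = np.array([1] * 8 + [-1] * 4)
            cost = m.class_cost_from_counts(y)
            model = m.train_weighted_linear_svm(X, y, 1.0, cost, loss="hinge")
            c = _sample_costs(y, 1.0, cost)
            ref = SVC(kernel="linear", C=1.0, tol=1e-10)
            ref.fit(X, y, sample_weight=c)
            w_ref, b_ref = ref.coef_[0], ref.intercept_[0]
            hinge = np.maximum(1.0 - y * (X @ w_ref + b_ref), 0.0)
            obj_ref = 0.5 * w_ref @ w_ref + c @ hinge
            assert model.objective <= obj_ref + 2e-6
            np.testing.assert_allclose(model.w, w_ref, atol=1e-3)

    def test_unknown_loss_rejected(self):
        X = np.array([[1.0], [-1.0]])
        with pytest.raises(ValueError):
            m.train_weighted_linear_svm(
                X, np.array([1, -1]), 1.0, {1: 1.0, -1: 1.0}, loss="logistic"
            )

    def test_rejects_bad_inputs(self):
        X = np.array([[1.0], [np.nan]])
        y = np.array([1, -1])
        with pytest.raises(ValueError):
            m.train_weighted_linear_svm(X, y, 1.0, {1: 1.0, -1: 1.0})
        with pytest.raises(ValueError):
            m.train_weighted_linear_svm(np.array([[1.0], [2.0]]), y, 0.0, {1: 1.0, -1: 1.0})


class TestPredict:
    def test_constant_classifier(self):
        model = m.LinearSVMModel(
            w=np.zeros(3), b=0.5, C=1.0, class_cost={1: 1.0, -1: 1.0}
        )
        labels, dec = m.predict(model, np.zeros((4, 3)))
        assert np.all(labels == 1) and np.all(dec == 0.5)

    def test_negation_flips_decisions(self):
        rng = np.random.default_rng(11)
        w = rng.standard_normal(4)
        a = m.LinearSVMModel(w=w, b=0.3, C=1.0, class_cost={1: 1.0, -1: 1.0})
        b = m.LinearSVMModel(w=-w, b=-0.3, C=1.0, class_cost={1: 1.0, -1: 1.0})
        X = rng.standard_normal((6, 4))
        _, da = m.predict(a, X)
        _, db = m.predict(b, X)
        np.testing.assert_allclose(da, -db, atol=1e-14)

    def test_zero_decision_reported_stable(self, caplog):
        model = m.LinearSVMModel(
            w=np.zeros(2), b=0.0, C=1.0, class_cost={1: 1.0, -1: 1.0}
        )
        import logging

        with caplog.at_level(logging.INFO, logger="mcisvm.svm"):
            label, dec = m.predict(model, np.array([1.0, 2.0]))
        assert label == 1 and dec == 0.0
        assert any("tie" in r.message or "0" in r.message for r in caplog.records)

    def test_dimension_mismatch(self):
        model = m.LinearSVMModel(
            w=np.zeros(2), b=0.0, C=1.0, class_cost={1: 1.0, -1: 1.0}
        )
        with pytest.raises(ValueError):
            m.predict(model, np.zeros(5))


class TestFoldPipelineAndSerialization:
    def test_fit_fold_model_uses_training_rows_only(self):
        X, y = _random_instance(12, n=20, p=40, imbalance=True)
        X[:, :5][y == -1] += 4.0  # make some columns selectable
        train = np.arange(16)
        model = m.fit_fold_model(X, y, train, C=1.0, alpha=0.05)
        X2 = X.copy()
        X2[17:] -= 123.0
        model2 = m.fit_fold_model(X2, y, train, C=1.0, alpha=0.05)
        np.testing.assert_array_equal(model.selection.keep, model2.selection.keep)
        np.testing.assert_array_equal(model.standardizer.mean, model2.standardizer.mean)
        np.testing.assert_allclose(model.w, model2.w)

    def test_model_round_trip(self, tmp_path):
        X, y = _random_instance(13, n=20, p=30, imbalance=True)
        X[:, :4][y == -1] += 4.0
        model = m.fit_fold_model(X, y, np.arange(20), C=2.0, alpha=0.05)
        m.save_model(model, tmp_path / "model")
        back = m.load_model(tmp_path / "model")
        x_new = np.random.default_rng(1).standard_normal(30)
        lab1, dec1 = m.predict(model, x_new)
        lab2, dec2 = m.predict(back, x_new)
        assert lab1 == lab2 and dec1 == pytest.approx(dec2, rel=1e-15)
        assert back.C == model.C and back.class_cost == model.class_cost
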