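import itertools

import numpy as np
import pandas as pd
import pytest

from amniotx.prediction import (
    KernelSpec,
    _nonneg_lasso_cd,
    auroc,
    consistent_selection,
    evaluate,
    fit_rf,
    gram_matrix,
    hsic_statistic,
    loocv,
    shs_select,
    stability,
    CVResult,
)
from conftest import make_expr


class TestHSIC:
    def test_constant_response_gives_exactly_zero(self, rng):
        K = gram_matrix(rng.normal(size=10))
        L = gram_matrix(np.full(10, 3.0))
        assert hsic_statistic(K, L) == pytest.approx(0.0, abs=1e-15)

    def test_equals_direct_trace_computation(self, rng):
        m = 5
        K = gram_matrix(rng.normal(size=m), KernelSpec("linear"))
        L = gram_matrix(rng.normal(size=m), KernelSpec("linear"))
        H = np.eye(m) - np.ones((m, m)) / m
        expected = np.trace(K @ H @ L @ H) / (m - 1) ** 2
        assert hsic_statistic(K, L) == pytest.approx(expected, rel=1e-12)

    def test_linear_kernel_statistic_is_squared_scaled_covariance(self, rng):
        # for linear kernels on centered variables, HSIC reduces to
        # (sum x_i y_i / (m-1))^2 = ((m-1) * cov(x, y))^2 / (m-1)^2
        m = 5
        x = rng.normal(size=m)
        y = rng.normal(size=m)
        K = gram_matrix(x, KernelSpec("linear"))
        L = gram_matrix(y, KernelSpec("linear"))
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) ** 2 / (m - 1) ** 2
        assert hsic_statistic(K, L) == pytest.approx(expected, rel=1e-12)

    def test_independent_variables_fall_below_permutation_null(self, rng):
        m = 200
        x, y = rng.normal(size=m), rng.normal(size=m)
        K, L = gram_matrix(x), gram_matrix(y)
        observed = hsic_statistic(K, L)
        null = []
        for _ in range(99):
            perm = rng.permutation(m)
            null.append(hsic_statistic(K, L[np.ix_(perm, perm)]))
        assert observed < np.quantile(null, 0.95)

    def test_gaussian_kernel_invariant_to_constant_shift(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        L = gram_matrix(y)
        a = hsic_statistic(gram_matrix(x), L)
        b = hsic_statistic(gram_matrix(x + 7.5), L)
        assert a == pytest.approx(b, rel=1e-12)

    def test_dependent_variables_exceed_null(self, rng):
        m = 100
        x = rng.normal(size=m)
        y = x ** 2 + 0.1 * rng.normal(size=m)   # nonlinear dependence
        K, L = gram_matrix(x), gram_matrix(y)
        observed = hsic_statistic(K, L)
        null = [hsic_statistic(K, L[np.ix_(p, p)])
                for p in (rng.permutation(m) for _ in range(99))]
        assert observed > np.quantile(null, 0.99)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            hsic_statistic(np.ones((1, 1)), np.ones((1, 1)))


class TestShsSelect:
    def test_planted_signal_gene_found_at_target_one(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 20))
            expr = make_expr(X)
            y = X[7].copy()                      # response IS gene 7
            sel = shs_select(expr, y, target_size=1, seed=seed)
            assert sel.selected == ["g7"]

    def test_duplicated_signal_gene_shares_weight(self, rng):
        X = rng.normal(size=(10, 24))
        X[3] = X[2]                              # duplicate under two ids
        expr = make_expr(X)
        y = X[2] + 0.05 * rng.normal(size=24)
        sel = shs_select(expr, y, target_size=2, seed=0)
        assert set(sel.selected) <= {"g2", "g3"}
        assert len(sel.selected) >= 1
        combined = sel.weights[["g2", "g3"]].sum()
        assert combined > 0.9 * sel.weights.sum()

    def test_full_shrinkage_empties_the_selection(self, rng):
        G = np.eye(4)
        c = rng.uniform(0.1, 1.0, size=4)
        alpha = _nonneg_lasso_cd(G, c, lam=10.0, alpha0=np.zeros(4))
        assert (alpha == 0).all()

    def test_constant_response_selects_nothing(self, rng):
        expr = make_expr(rng.normal(size=(8, 10)))
        with pytest.warns(UserWarning, match="constant response"):
            sel = shs_select(expr, np.full(10, 2.0), target_size=3)
        assert sel.selected == []

    def test_support_respects_target_size(self, rng):
        X = rng.normal(size=(40, 16))
        y = X[:5].sum(axis=0) + 0.2 * rng.normal(size=16)
        sel = shs_select(make_expr(X), y, target_size=6, seed=0)
        assert 1 <= len(sel.selected) <= 6
        assert (sel.weights[sel.selected] > 0).all()

    def test_deterministic_given_inputs(self, rng):
        X = rng.normal(size=(15, 12))
        y = rng.normal(size=12)
        a = shs_select(make_expr(X), y, target_size=4, seed=1)
        b = shs_select(make_expr(X), y, target_size=4, seed=1)
        assert a.selected == b.selected
        assert np.allclose(a.weights, b.weights)

    def test_nonfinite_input_rejected(self, rng):
        X = rng.normal(size=(6, 10))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            shs_select(make_expr(X), np.arange(10.0), target_size=2)


class TestRandomForest:
    def test_constant_response_predicts_the_constant(self, rng):
        expr = make_expr(rng.normal(size=(3, 20)))
        model = fit_rf(expr, np.full(20, 4.2), n_trees=50, seed=0)
        pred = model.predict(rng.normal(size=(5, 3)))
        assert np.allclose(pred, 4.2)

    def test_step_function_signal_is_learnable(self, rng):
        n = 200
        x = rng.normal(size=(1, n))
        y = np.where(x[0] > 0, 5.0, 1.0)
        model = fit_rf(make_expr(x), y, n_trees=300, seed=0)
        model_oob = fit_rf(make_expr(x), y, n_trees=300, seed=0)
        pred = model.predict(x.T)
        r2 = 1 - np.sum((pred - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.8
        assert np.allclose(pred, model_oob.predict(x.T))  # same seed, same trees

    def test_same_seed_gives_identical_predictions(self, rng):
        expr = make_expr(rng.normal(size=(5, 30)))
        y = rng.normal(size=30)
        a = fit_rf(expr, y, n_trees=100, seed=7).predict(expr.to_numpy().T)
        b = fit_rf(expr, y, n_trees=100, seed=7).predict(expr.to_numpy().T)
        assert np.array_equal(a, b)


class TestLoocv:
    def test_constant_response_predicts_perfectly(self, rng):
        expr = make_expr(rng.normal(size=(6, 8)))
        with pytest.warns(UserWarning):         # constant response -> empty sel
            cv = loocv(expr, np.full(8, 3.0), target_size=2, n_trees=20, seed=0)
        assert np.allclose(cv.predictions, 3.0)
        m = evaluate(cv, np.full(8, 3.0))
        assert m.rmse == pytest.approx(0.0)

    def test_one_prediction_per_sample_and_fold_count(self, rng):
        X = rng.normal(size=(15, 10))
        y = X[0] + 0.1 * rng.normal(size=10)
        cv = loocv(make_expr(X), y, target_size=3, n_trees=30, seed=0)
        assert len(cv.predictions) == 10
        assert len(cv.fold_selections) == 10

    def test_no_leakage_held_out_response_cannot_influence_fold(self, rng):
        """Corrupting the held-out sample's response must leave that fold's
        selection, model, and prediction unchanged."""
        X = rng.normal(size=(20, 12))
        y = X[1] + 0.2 * rng.normal(size=12)
        cv = loocv(make_expr(X), y, target_size=3, n_trees=30, seed=5)
        i = 4
        y_bug = y.copy()
        y_bug[i] = 1e6                           # absurd held-out response
        cv_bug = loocv(make_expr(X), y_bug, target_size=3, n_trees=30, seed=5)
        assert cv.fold_selections[i].selected == cv_bug.fold_selections[i].selected
        assert cv.predictions[i] == pytest.approx(cv_bug.predictions[i])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            loocv(make_expr(rng.normal(size=(4, 4))), np.arange(4.0), 1, 10, 0)


def auroc_by_pair_counting(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    if not pos or not neg:
        return None
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def _cv(self, predictions):
        n = len(predictions)
        return CVResult(sample_ids=[f"s{i}" for i in range(n)],
                        predictions=np.asarray(predictions, dtype=float),
                        fold_selections=[], seed=0)

    def test_perfect_predictions(self):
        ttd = np.array([0.05, 0.1, 0.5, 1.5, 3.0, 6.0])
        m = evaluate(self._cv(ttd), ttd)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0)
        assert all(v == pytest.approx(1.0) for v in m.auroc.values())

    def test_constant_predictions_give_half_auroc(self):
        ttd = np.array([0.05, 0.1, 0.5, 1.5, 3.0, 6.0])
        m = evaluate(self._cv(np.full(6, 2.0)), ttd)
        assert all(v == pytest.approx(0.5) for v in m.auroc.values())

    def test_single_class_horizon_reported_missing(self):
        ttd = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        m = evaluate(self._cv(ttd), ttd, horizons=[1.0])
        assert m.auroc[1.0] is None

    def test_worked_pair_counting_example(self):
        # scores (1, 2, 3, 4) with labels (1, 1, 0, 0): every positive
        # outranks every negative when score = -prediction
        assert auroc(np.array([1, 2, 3, 4.0]),
                     np.array([True, True, False, False])) == pytest.approx(0.0)
        assert auroc(-np.array([1, 2, 3, 4.0]),
                     np.array([True, True, False, False])) == pytest.approx(1.0)

    def test_auroc_equals_exhaustive_pair_counting(self, rng):
        for _ in range(100):
            n = rng.integers(2, 13)
            scores = rng.integers(0, 4, size=n).astype(float)  # force ties
            labels = rng.integers(0, 2, size=n).astype(bool)
            expected = auroc_by_pair_counting(scores, labels)
            got = auroc(scores, labels)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_auroc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50).astype(bool)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


class TestStability:
    def test_identical_sets_perfect_agreement(self):
        universe = [f"g{i}" for i in range(10)]
        rep = stability([{"g0", "g1"}, {"g0", "g1"}], universe)
        assert rep.mean_jaccard == pytest.approx(1.0)
        assert rep.mean_kappa == pytest.approx(1.0)

    def test_disjoint_sets_zero_jaccard(self):
        universe = [f"g{i}" for i in range(10)]
        rep = stability([{"g0"}, {"g1"}], universe)
        assert rep.mean_jaccard == pytest.approx(0.0)

    def test_hand_worked_kappa(self):
        # A = {a,b,c}, B = {b,c,d} on a 10-gene universe:
        # po = 0.8, pe = 0.3*0.3 + 0.7*0.7 = 0.58, kappa = 0.22/0.42
        universe = list("abcdefghij")
        rep = stability([set("abc"), set("bcd")], universe)
        assert rep.mean_jaccard == pytest.approx(0.5)
        assert rep.mean_kappa == pytest.approx((0.8 - 0.58) / 0.42)

    def test_selection_frequency(self):
        universe = ["a", "b", "c"]
        rep = stability([{"a"}, {"a", "b"}], universe)
        assert rep.selection_frequency["a"] == pytest.approx(1.0)
        assert rep.selection_frequency["b"] == pytest.approx(0.5)
        assert rep.selection_frequency["c"] == pytest.approx(0.0)


class TestConsistentSelection:
    def test_always_selected_gene_retained(self):
        universe = [f"g{i}" for i in range(100)]
        folds = [{"g0", f"g{10 + i % 5}"} for i in range(38)]
        rep = consistent_selection(folds, universe)
        assert "g0" in rep.consensus_genes
        assert rep.always_selected == ["g0"]

    def test_rarely_selected_gene_dropped(self):
        universe = [f"g{i}" for i in range(100)]
        folds = [{"g0"}] * 37 + [{"g0", "g99"}]
        rep = consistent_selection(folds, universe)
        assert "g99" not in rep.consensus_genes

    def test_planted_consensus_recovered_across_seeds(self):
        """Five always-selected planted genes plus uniform noise selections:
        the consensus equals exactly the planted set in >= 95% of seeds."""
        universe = [f"g{i}" for i in range(100)]
        planted = set(universe[:5])
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            folds = [planted | set(rng.choice(universe[5:], size=5,
                                              replace=False))
                     for _ in range(10)]
            rep = consistent_selection(folds, universe)
            hits += set(rep.consensus_genes) == planted
        assert hits >= 19
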