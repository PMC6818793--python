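"""Logistic MLE, cross-validation mechanics, ROC, AIC and subset search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinrisk as kr
from kinrisk.models import (
    FitError,
    ModelSpec,
    SeparationError,
    logistic_mle,
    make_folds,
    pool_predictors,
    select_subsample,
)

from conftest import oracle_auc, oracle_bernoulli_loglik


def _sim_logit(rng, n, alphas, alpha0):
    X = rng.normal(size=(n, len(alphas)))
    eta = alpha0 + X @ np.array(alphas)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def _as_table(X, y, names):
    t = pd.DataFrame(X, columns=names)
    t["ec"] = y
    t["child_id"] = [f"c{i}" for i in range(len(y))]
    t["seq"] = 1
    return t


class TestROC:
    def test_constant_scores_give_exactly_half(self):
        auc, _ = kr.roc_score([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3])
        assert auc == 0.5

    def test_perfect_separation_gives_exactly_one(self):
        auc, _ = kr.roc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_hand_fixture_matches_pair_counting(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]
        auc, _ = kr.roc_score(labels, scores)
        assert auc == oracle_auc(labels, scores) == 0.75

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.integers(0, 5, size=n) / 4.0  # coarse grid forces ties
        auc, _ = kr.roc_score(labels, scores)
        assert auc == pytest.approx(oracle_auc(labels.tolist(), scores.tolist()), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=100)
        labels[0], labels[1] = 0, 1
        scores = rng.random(100)
        a1, _ = kr.roc_score(labels, scores)
        a2, _ = kr.roc_score(labels, -scores)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="single class"):
            kr.roc_score([1, 1, 1], [0.1, 0.2, 0.3])


class TestAIC:
    def test_zero_loglik_zero_params(self):
        assert kr.aic(0.0, 0) == 0.0

    def test_intercept_only_balanced_closed_form(self):
        n = 400
        y = np.array([0, 1] * (n // 2), dtype=float)
        X = np.empty((n, 0))
        beta, loglik, _ = logistic_mle(X, y)
        assert beta[0] == pytest.approx(0.0, abs=1e-7)
        assert kr.aic(loglik, 1) == pytest.approx(2 + 2 * n * np.log(2), abs=1e-6)

    def test_aic_matches_independent_likelihood_evaluation(self):
        rng = np.random.default_rng(7)
        X, y = _sim_logit(rng, 500, [0.8, -0.5], -0.4)
        beta, loglik, _ = logistic_mle(X, y)
        assert loglik == pytest.approx(oracle_bernoulli_loglik(X, y, beta), abs=1e-6)
        assert kr.aic(loglik, 3) == pytest.approx(2 * 3 - 2 * loglik, abs=1e-12)

    def test_noise_predictor_raises_aic_in_expectation(self):
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(12):
            X, y = _sim_logit(rng, 800, [0.7], -0.5)
            noise = rng.normal(size=(800, 1))
            _, l1, _ = logistic_mle(X, y)
            _, l2, _ = logistic_mle(np.hstack([X, noise]), y)
            diffs.append(kr.aic(l2, 3) - kr.aic(l1, 2))
        assert np.mean(diffs) > 0


class TestLogisticMLE:
    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X, y = _sim_logit(rng, 2000, [0.8, -0.5, 0.2], -1.0)
        beta, loglik, cov = logistic_mle(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)
        assert loglik == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-4)

    def test_parameter_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(19)
        truth = [-2.0, 0.8, -0.5]
        X, y = _sim_logit(rng, 20_000, truth[1:], truth[0])
        beta, _, cov = logistic_mle(X, y)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(beta - truth) < 3 * se)

    def test_complete_separation_raises_advice(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]] * 10)
        y = (X[:, 0] > 0).astype(float)
        with pytest.raises(SeparationError, match="penalised"):
            logistic_mle(X, y)

    def test_single_class_response_is_an_error(self):
        with pytest.raises(FitError):
            logistic_mle(np.zeros((5, 1)), np.ones(5))


class TestCrossValidation:
    def test_every_case_held_out_once_with_balanced_folds(self):
        folds = make_folds(1000, 10, seed=4)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 1000
        assert sizes.max() - sizes.min() <= 1

    def test_grouped_folds_keep_children_together(self):
        groups = np.repeat(np.arange(50), 4)
        folds = make_folds(200, 5, seed=1, groups=groups)
        for g in range(50):
            assert len(set(folds[groups == g])) == 1

    def test_leave_one_out_matches_hand_coded_loop(self):
        rng = np.random.default_rng(23)
        X, y = _sim_logit(rng, 30, [0.9], -0.2)
        table = _as_table(X, y, ["nNotes"])
        res = kr.fit_logistic_cv(table, ModelSpec(("nNotes",)), K=15, seed=0)
        # direct LOO-style loop over the same folds
        expected = np.empty(len(y))
        for k in range(15):
            test = res.fold_ids == k
            beta, _, _ = logistic_mle(X[~test], y[~test])
            expected[test] = 1 / (1 + np.exp(-(beta[0] + X[test] @ beta[1:])))
        np.testing.assert_allclose(res.oof_scores, expected, atol=1e-10)

    def test_coefficient_recovery_through_cv_interface(self):
        rng = np.random.default_rng(29)
        X, y = _sim_logit(rng, 30_000, [0.8, -0.5], -2.0)
        table = _as_table(X, y, ["nNotes", "nNeighsR"])
        res = kr.fit_logistic_cv(table, ModelSpec(("nNotes", "nNeighsR")), K=10, seed=0)
        assert abs(res.alphas["nNotes"] - 0.8) < 3 * res.std_errors["nNotes"]
        assert abs(res.alphas["nNeighsR"] + 0.5) < 3 * res.std_errors["nNeighsR"]
        assert abs(res.alpha0 + 2.0) < 3 * res.std_errors["(intercept)"]
        assert res.roc_score > 0.6

    def test_full_pool_loglik_dominates_subsets(self, small_feature_table):
        _, table = small_feature_table
        full = kr.fit_logistic_cv(
            table, ModelSpec(tuple(["age"] + pool_predictors("all", "all"))), K=5, seed=0
        )
        sub = kr.fit_logistic_cv(table, ModelSpec(("age", "nNotes", "nWithNotesW")), K=5, seed=0)
        assert full.loglik >= sub.loglik - 1e-8


class TestModelSpec:
    def test_event_features_banned_for_first_notifications(self):
        with pytest.raises(ValueError, match="first-notification"):
            ModelSpec(("age", "nNotes"), subsample="first")

    def test_predictors_must_come_from_pool(self):
        with pytest.raises(ValueError, match="outside pool"):
            ModelSpec(("age", "nWithNotesW"), variable_pool="events_plus_recorded")

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError, match="unknown predictors"):
            ModelSpec(("age", "nReferrals"))


class TestBestSubsetSearch:
    def test_three_predictor_pool_yields_single_four_variable_candidate(self, small_feature_table):
        _, table = small_feature_table
        ranked = kr.best_subset_search(table, "all", "first", K=5, seed=0)
        wl_only = [r for r in ranked if r.spec.m == 4]
        # first-notification pool = 7 network features -> C(7,3)=35 4-var models
        assert len(wl_only) == 35
        assert all(r.spec.predictor_names[0] == "age" for r in ranked)

    def test_ranking_is_by_roc_descending(self, small_feature_table):
        _, table = small_feature_table
        ranked = kr.best_subset_search(table, "events_only", "all", K=5, seed=0)
        rocs = [r.roc_score for r in ranked]
        assert rocs == sorted(rocs, reverse=True)

    def test_results_invariant_to_predictor_column_order(self, small_feature_table):
        _, table = small_feature_table
        shuffled = table[list(table.columns[:4]) + list(reversed(kr.FEATURE_NAMES))]
        a = kr.best_subset_search(table, "events_only", "all", K=5, seed=0)
        b = kr.best_subset_search(shuffled, "events_only", "all", K=5, seed=0)
        assert [r.spec.predictor_names for r in a] == [r.spec.predictor_names for r in b]
        assert [r.roc_score for r in a] == pytest.approx([r.roc_score for r in b])

    def test_null_scenario_fits_are_null(self):
        """On a registry with zero risk effects the network coefficients sit
        within 3 SE of zero and the pooled out-of-fold ROC is ~0.5."""
        cfg = kr.synthetic_data.override(kr.scenario("null_risk", seed=37), n_families=1200)
        db = kr.generate(cfg)
        notes = kr.assemble_notifications(db)
        cases = kr.label_notifications(db, notes)
        table = kr.feature_matrix(db, cases)
        names = tuple(["age"] + pool_predictors("all", "all"))
        res = kr.fit_logistic_cv(table, ModelSpec(names), K=10, seed=0)
        network = [n for n in names if n.endswith(("R", "W"))]
        within = [abs(res.alphas[n]) < 3 * res.std_errors[n] for n in network]
        assert sum(within) >= len(network) - 1  # allow one 3-sigma excursion
        n1 = int(table["ec"].sum())
        n0 = len(table) - n1
        se_auc = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(res.roc_score - 0.5) < 3 * se_auc + 0.01  # slight CV pessimism allowed

    def test_select_subsample_partitions(self, small_feature_table):
        _, table = small_feature_table
        first = select_subsample(table, "first")
        sub = select_subsample(table, "subsequent")
        assert len(first) + len(sub) == len(table)
        assert (first["seq"] == 1).all() and (sub["seq"] > 1).all()
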