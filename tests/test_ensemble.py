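"""Voting/stacking ensembles, weight search, CV, backward elimination."""

import itertools

import numpy as np
import pandas as pd
import pytest

from painrank.ensemble import (
    BaseLearnerSpec,
    StackingEnsemble,
    VotingEnsemble,
    WeightVector,
    backward_eliminate,
    cross_validate,
    default_learner_specs,
    fit_base_learners,
    oof_probabilities,
    predict_proba_matrix,
    random_search_tuner,
    shap_weighted,
    soft_vote,
    weight_search,
)
from painrank.metrics import confusion_from_predictions, metric_set


def separable_data(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2))
    X[:, 0] += 10.0 * y  # fully separated along feature 0
    return X, y


def small_specs(seed=0):
    """Cheap learners for unit tests."""
    return [
        BaseLearnerSpec("xgb", "xgb", {"n_estimators": 20, "max_depth": 3}, seed),
        BaseLearnerSpec("gb", "gb", {"n_estimators": 20, "max_depth": 2}, seed),
        BaseLearnerSpec("ada", "ada", {"n_estimators": 20}, seed),
        BaseLearnerSpec("rf", "rf", {"n_estimators": 30}, seed),
    ]


class TestSoftVote:
    def test_identical_learners_any_weights(self):
        p = np.array([0.2, 0.7, 0.9])
        out = soft_vote([p, p, p], (5, 1, 2))
        np.testing.assert_allclose(out, p)

    def test_hand_weighted_mean(self):
        out = soft_vote([np.array([0.2]), np.array([0.8])], (1, 3))
        assert out[0] == pytest.approx(0.65)

    def test_paper_weight_configuration_hand_average(self):
        probs = [np.array([0.9]), np.array([0.1]), np.array([0.5]), np.array([0.3])]
        out = soft_vote(probs, (4, 2, 1, 3))
        assert out[0] == pytest.approx((4 * 0.9 + 2 * 0.1 + 1 * 0.5 + 3 * 0.3) / 10)

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(size=(50, 4))
        np.testing.assert_allclose(soft_vote(P, (4, 2, 1, 3)),
                                   soft_vote(P, (8, 4, 2, 6)), atol=1e-15)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightVector((0, 0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_vote(np.ones((5, 3)), (1, 2))


class TestWeightSearch:
    def test_single_learner_trivial(self):
        truth = np.array([1, 0, 1, 0])
        probas = np.array([[0.9], [0.1], [0.8], [0.2]])
        assert weight_search(probas, truth, (7,)).weights == (7,)

    def test_perfect_learner_gets_largest_weight(self):
        truth = np.array([1, 0, 1, 0, 1, 0])
        good = np.array([0.9, 0.1, 0.8, 0.2, 0.95, 0.05])
        bad = 1.0 - good  # anticorrelated
        w = weight_search(np.column_stack([good, bad]), truth, (4, 1))
        assert w.weights == (4, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, size=40)
        P = rng.uniform(size=(40, 4))
        chosen = weight_search(P, truth, (4, 2, 1, 3))

        def gm_of(perm):
            combined = P @ (np.array(perm) / sum(perm))
            return metric_set(confusion_from_predictions(
                truth, (combined >= 0.5).astype(int))).gm

        best = max(gm_of(p) for p in set(itertools.permutations((4, 2, 1, 3))))
        assert gm_of(chosen.weights) == pytest.approx(best, abs=1e-12)

    def test_tie_broken_lexicographically(self):
        truth = np.array([1, 0])
        P = np.full((2, 2), 0.5)  # every permutation scores identically
        w = weight_search(P, truth, (2, 1))
        assert w.weights == (1, 2)  # first in lexicographic enumeration


class TestBaseLearners:
    def test_separable_data_training_gm_is_one(self):
        X, y = separable_data()
        learners = fit_base_learners(X, y, small_specs())
        for name, m in learners.items():
            pred = (m.predict_proba(X)[:, 1] >= 0.5).astype(int)
            g = metric_set(confusion_from_predictions(y, pred)).gm
            assert g == pytest.approx(1.0), name

    def test_deterministic_under_seed(self):
        X, y = separable_data(seed=3)
        p1 = predict_proba_matrix(fit_base_learners(X, y, small_specs(9)), X)
        p2 = predict_proba_matrix(fit_base_learners(X, y, small_specs(9)), X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError):
            fit_base_learners(X, np.zeros(20, dtype=int), small_specs())

    def test_empty_specs_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError):
            fit_base_learners(X, y, [])


class TestCrossValidation:
    def test_separable_data_all_folds_perfect(self):
        X, y = separable_data(n=200)
        cv = cross_validate(X, y, lambda: VotingEnsemble(
            small_specs(), tune_weights=False), folds=5, seed=0)
        for fold in cv.folds:
            assert fold.gm == pytest.approx(1.0)

    def test_reproducible_fold_assignment(self):
        X, y = separable_data(n=100, seed=2)
        f = lambda: VotingEnsemble(small_specs(), tune_weights=False)
        a = cross_validate(X, y, f, folds=4, seed=7)
        b = cross_validate(X, y, f, folds=4, seed=7)
        for (ia, ta, pa), (ib, tb, pb) in zip(a.predictions, b.predictions):
            np.testing.assert_array_equal(ia, ib)
            np.testing.assert_array_equal(pa, pb)

    def test_fold_metrics_recompute_from_stored_predictions(self):
        X, y = separable_data(n=100, seed=4)
        cv = cross_validate(X, y, lambda: VotingEnsemble(
            small_specs(), tune_weights=False), folds=4, seed=1)
        for fold_metrics, (idx, truth, proba) in zip(cv.folds, cv.predictions):
            again = metric_set(confusion_from_predictions(
                truth, (proba >= 0.5).astype(int)))
            assert again == fold_metrics

    def test_too_few_positives_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        y = np.array([1] * 3 + [0] * 27)
        with pytest.raises(ValueError):
            cross_validate(X, y, lambda: VotingEnsemble(small_specs()), folds=5)

    def test_mean_sd_recompute_from_fold_list(self):
        X, y = separable_data(n=100, seed=5)
        cv = cross_validate(X, y, lambda: VotingEnsemble(
            small_specs(), tune_weights=False), folds=4, seed=2)
        gms = [f.gm for f in cv.folds]
        assert cv.mean().gm == pytest.approx(np.mean(gms))
        assert cv.sd().gm == pytest.approx(np.std(gms, ddof=1))


class TestStacking:
    def test_separable_training_gm_one(self):
        X, y = separable_data(n=160)
        m = StackingEnsemble(small_specs(), oof_folds=4).fit(X, y)
        pred = m.predict(X)
        assert metric_set(confusion_from_predictions(y, pred)).gm == pytest.approx(1.0)

    def test_probability_rows_sum_to_one(self):
        X, y = separable_data(n=80, seed=6)
        m = StackingEnsemble(small_specs(), oof_folds=4).fit(X, y)
        np.testing.assert_allclose(m.predict_proba(X).sum(axis=1), 1.0, atol=1e-12)

    def test_complementary_learners_beat_best_individual(self):
        # XOR-style structure that no axis-aligned shallow stump solves alone
        rng = np.random.default_rng(11)
        n = 400
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = (a ^ b).astype(int)
        X = np.column_stack([a + rng.normal(scale=0.1, size=n),
                             b + rng.normal(scale=0.1, size=n)])
        specs = small_specs(3)
        m = StackingEnsemble(specs, oof_folds=4, seed=3).fit(X, y)
        stack_gm = metric_set(confusion_from_predictions(y, m.predict(X))).gm
        singles = []
        for name, est in m.learners_.items():
            pred = (est.predict_proba(X)[:, 1] >= 0.5).astype(int)
            singles.append(metric_set(confusion_from_predictions(y, pred)).gm)
        assert stack_gm >= max(singles) - 1e-9


class TestVotingEnsemble:
    def test_probability_rows_sum_to_one(self):
        X, y = separable_data(n=80, seed=7)
        m = VotingEnsemble(small_specs(), tune_weights=False).fit(X, y)
        P = m.predict_proba(X)
        assert P.min() >= 0 and P.max() <= 1
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_weight_search_runs_on_oof_probabilities(self):
        X, y = separable_data(n=120, seed=8)
        m = VotingEnsemble(small_specs(), oof_folds=4).fit(X, y)
        assert sorted(m.weights_.weights) == [1, 2, 3, 4]

    def test_attributions_shape(self):
        X, y = separable_data(n=80, seed=9)
        m = VotingEnsemble(small_specs(), tune_weights=False).fit(X, y)
        contrib = m.attributions(X[:10])
        assert contrib.shape == (10, X.shape[1])


class TestShapWeighted:
    def test_equal_matrices(self):
        m = np.ones((4, 3))
        np.testing.assert_allclose(shap_weighted([m, m], WeightVector((4, 2))), m)

    def test_hand_weighted(self):
        a = np.array([[2.0, 0.0]])
        b = np.array([[0.0, 3.0]])
        np.testing.assert_allclose(shap_weighted([a, b], (1, 1)),
                                   np.array([[1.0, 1.5]]))


class TestBackwardElimination:
    def test_recovers_planted_informative_feature(self):
        rng = np.random.default_rng(12)
        n = 240
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({
            "signal": y * 4.0 + rng.normal(scale=0.8, size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
            "noise3": rng.normal(size=n),
        })
        selected, traj = backward_eliminate(
            X, y, lambda: VotingEnsemble(small_specs(), tune_weights=False),
            folds=3, seed=0)
        assert "signal" in selected
        assert traj["n_features"].tolist() == [4, 3, 2, 1]

    def test_selected_subset_maximizes_trajectory_gm(self):
        rng = np.random.default_rng(13)
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        X["a"] += y * 3.0
        selected, traj = backward_eliminate(
            X, y, lambda: VotingEnsemble(small_specs(), tune_weights=False),
            folds=3, seed=1)
        ok = traj[~traj["failed"]]
        best_gm = ok["gm"].max()
        row = ok[ok["features"].map(tuple) == tuple(selected)]
        assert row["gm"].iloc[0] == pytest.approx(best_gm)

    def test_single_feature_input_rejected(self):
        X = pd.DataFrame({"only": [1.0, 2.0]})
        with pytest.raises(ValueError):
            backward_eliminate(X, np.array([0, 1]), lambda: None)


class TestTuner:
    def test_random_search_improves_over_worst_candidate(self):
        X, y = separable_data(n=120, seed=14)
        hp, obj = random_search_tuner(
            X, y, "rf", {"n_estimators": [10, 30], "max_depth": [1, 3]},
            budget=4, folds=3, seed=0)
        assert set(hp) == {"n_estimators", "max_depth"}
        assert obj > 2.0  # separable: summed four-metric objective near 4


class TestNullBehaviour:
    def test_pure_noise_features_give_chance_level_metrics(self):
        rng = np.random.default_rng(20)
        n = 820  # 20 positives at 1:40
        y = np.array([1] * 20 + [0] * 800)
        X = rng.normal(size=(n, 6))
        cv = cross_validate(X, y, lambda: VotingEnsemble(
            small_specs(), tune_weights=False), folds=5, seed=0)
        m = cv.mean()
        assert 0.35 <= m.ba <= 0.65
        assert m.gm <= 0.7


class TestOofProbabilities:
    def test_shape_and_range(self):
        X, y = separable_data(n=100, seed=15)
        oof = oof_probabilities(X, y, small_specs(), folds=4, seed=0)
        assert oof.shape == (100, 4)
        assert oof.min() >= 0 and oof.max() <= 1

    def test_default_specs_have_fixed_member_order(self):
        assert [s.name for s in default_learner_specs()] == ["xgb", "gb", "ada", "rf"]
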