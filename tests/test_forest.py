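"""Chi-squared split selection, surrogate routing, OOB machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from emavar.forest import (ForestParams, chi2_split_pvalue, feature_importance,
                           fit_forest, forward_select, gini_impurity,
                           hyperparam_search, oob_fraction, oob_predict,
                           roc_auc_ci, _predict_row)


def separable_frame(rng, n=100, n_noise=1):
    flag = rng.random(n) < 0.5
    df = pd.DataFrame({"sep": flag.astype(float)})
    for j in range(n_noise):
        df[f"noise{j}"] = rng.standard_normal(n)
    y = np.where(flag, "high", "low")
    return df, y


class TestChi2Split:
    def test_hand_chi2_on_2x2_table(self):
        # table [[20,5],[5,20]]: chi2 = 18, p = P(chi2_1 > 18) ~ 2.21e-5
        x = np.array(["a"] * 25 + ["b"] * 25)
        y = np.array([0] * 20 + [1] * 5 + [0] * 5 + [1] * 20)
        p = chi2_split_pvalue(x, y)
        assert p == pytest.approx(2.209e-5, rel=1e-3)

    def test_independent_table_gives_p_one(self):
        x = np.array(["a"] * 20 + ["b"] * 20)
        y = np.array(([0] * 10 + [1] * 10) * 2)
        assert chi2_split_pvalue(x, y) == pytest.approx(1.0)

    def test_constant_feature_gives_p_one(self):
        assert chi2_split_pvalue(np.ones(30), np.arange(30) % 2) == 1.0

    def test_numeric_feature_identical_in_both_classes(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(20):
            x = rng.standard_normal(100)
            y = rng.integers(0, 2, 100)
            ps.append(chi2_split_pvalue(x, y))
        assert np.mean(ps) > 0.3  # null: no systematic association

    def test_missing_values_excluded(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, np.nan, np.nan])
        y = np.array([0, 0, 1, 1, 0, 1])
        assert chi2_split_pvalue(x, y) < 0.2


class TestGini:
    def test_stump_decrease_hand_value(self):
        # parent 25/25 -> children 20/5 and 5/20: 0.5 - 0.32 = 0.18
        parent = gini_impurity(np.array([25, 25]))
        child = gini_impurity(np.array([20, 5]))
        assert parent == pytest.approx(0.5)
        assert child == pytest.approx(0.32)
        assert parent - (25 / 50 * child + 25 / 50 * child) == pytest.approx(0.18)


class TestGrowAndPredict:
    def test_perfect_binary_feature_gives_depth_one_tree(self):
        rng = np.random.default_rng(1)
        df, y = separable_frame(rng, n=80, n_noise=0)
        forest = fit_forest(df, y, ForestParams(n_trees=5, min_leaf=2), seed=1)
        for tree in forest.trees:
            assert not tree.is_leaf
            assert tree.left.is_leaf and tree.right.is_leaf
        scores = forest.predict_proba(df)
        assert roc_auc_score((np.asarray(y) == "high").astype(int), scores) == 1.0

    def test_duplicate_feature_becomes_perfect_surrogate(self):
        rng = np.random.default_rng(2)
        df, y = separable_frame(rng, n=80, n_noise=0)
        df["copy"] = df["sep"]
        forest = fit_forest(df, y, ForestParams(n_trees=10, min_leaf=2,
                                                mtry=2), seed=2)
        found = False
        for tree in forest.trees:
            for s in tree.surrogates:
                if s.agreement == pytest.approx(1.0):
                    found = True
        assert found

    def test_single_tree_forest_equals_its_tree(self):
        rng = np.random.default_rng(3)
        df, y = separable_frame(rng, n=60)
        forest = fit_forest(df, y, ForestParams(n_trees=1), seed=3)
        probs = forest.predict_proba(df)
        direct = [_predict_row(forest.trees[0], forest.columns, i)
                  for i in range(len(df))]
        np.testing.assert_allclose(probs, direct)

    def test_missing_split_feature_routed_by_surrogate(self):
        rng = np.random.default_rng(4)
        n = 150
        z = rng.standard_normal(n)
        y = np.where(z > 0, "high", "low")
        x1 = z.copy()
        x1[rng.random(n) < 0.5] = np.nan
        df = pd.DataFrame({"x1": x1, "proxy": z + rng.normal(0, 0.05, n)})
        forest = fit_forest(df, y, ForestParams(n_trees=20), seed=4)
        scores = oob_predict(forest)
        auc = roc_auc_score((np.asarray(y) == "high").astype(int), scores)
        assert auc > 0.95

    def test_monotone_transform_leaves_predictions_unchanged(self):
        """Splits depend only on feature order, so exp() changes nothing."""
        rng = np.random.default_rng(5)
        n = 100
        x = rng.standard_normal(n)
        y = np.where(x + rng.normal(0, 0.5, n) > 0, "high", "low")
        df1 = pd.DataFrame({"x": x, "z": rng.standard_normal(n)})
        df2 = df1.copy()
        df2["x"] = np.exp(df2["x"])
        f1 = fit_forest(df1, y, ForestParams(n_trees=15), seed=5)
        f2 = fit_forest(df2, y, ForestParams(n_trees=15), seed=5)
        np.testing.assert_allclose(oob_predict(f1), oob_predict(f2))

    def test_sklearn_oracle_agreement_on_separable_fixture(self):
        """Without missing data both forests classify the fixture
        identically (independent standard bagged-forest oracle)."""
        rng = np.random.default_rng(6)
        df, y = separable_frame(rng, n=80)
        ours = fit_forest(df, y, ForestParams(n_trees=25,
                                              use_surrogates=False), seed=6)
        pred_ours = (ours.predict_proba(df) > 0.5)
        sk = RandomForestClassifier(n_estimators=25, random_state=0)
        sk.fit(df.to_numpy(), y)
        pred_sk = sk.predict(df.to_numpy()) == "high"
        assert np.array_equal(pred_ours, pred_sk)


class TestOob:
    def test_oob_fraction_near_one_over_e(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"a": rng.standard_normal(200)})
        y = np.where(rng.random(200) < 0.5, "high", "low")
        forest = fit_forest(df, y, ForestParams(n_trees=300, min_leaf=200),
                            seed=7)
        assert oob_fraction(forest) == pytest.approx((1 - 1 / 200) ** 200,
                                                     abs=0.01)

    def test_every_patient_oob_somewhere_with_enough_trees(self):
        rng = np.random.default_rng(8)
        df, y = separable_frame(rng, n=60)
        forest = fit_forest(df, y, ForestParams(n_trees=50), seed=8)
        assert forest.oob_mask().any(axis=0).all()

    def test_oob_scores_equal_per_tree_vote_average(self):
        """Compositional oracle: re-aggregate votes tree by tree."""
        rng = np.random.default_rng(9)
        df, y = separable_frame(rng, n=30)
        forest = fit_forest(df, y, ForestParams(n_trees=5, min_leaf=3), seed=9)
        scores = oob_predict(forest)
        oob = forest.oob_mask()
        for i in range(len(df)):
            votes = [_predict_row(forest.trees[t], forest.columns, i)
                     for t in range(5) if oob[t, i]]
            if votes:
                assert scores[i] == pytest.approx(np.mean(votes))
            else:
                assert np.isnan(scores[i])

    def test_never_oob_patient_gets_missing_score(self):
        rng = np.random.default_rng(10)
        df, y = separable_frame(rng, n=25)
        forest = fit_forest(df, y, ForestParams(n_trees=2, min_leaf=3), seed=3)
        forest.inbag[:, 0] = 1  # force patient 0 in-bag everywhere
        with pytest.warns(UserWarning, match="never out of bag"):
            scores = oob_predict(forest)
        assert np.isnan(scores[0])


class TestRocAuc:
    def test_exhaustive_pair_count_example(self):
        res = roc_auc_ci([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=100,
                         seed=0)
        assert res.auc == pytest.approx(0.75)

    def test_perfect_scores_give_unit_auc_and_degenerate_ci(self):
        res = roc_auc_ci([0, 0, 1, 1], [0, 0, 1, 1], n_boot=200, seed=1)
        assert res.auc == 1.0
        assert res.ci == (1.0, 1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        res = roc_auc_ci(rng.random(4000), rng.integers(0, 2, 4000),
                         n_boot=100, seed=2)
        assert res.auc == pytest.approx(0.5, abs=0.03)
        assert res.ci[0] <= res.auc <= res.ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_ci([0.2, 0.8], [1, 1], n_boot=10, seed=0)


class TestForwardSelect:
    def test_duplicate_of_selected_feature_never_added(self):
        rng = np.random.default_rng(12)
        df, y = separable_frame(rng, n=80, n_noise=0)
        df["dup"] = df["sep"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel, trace = forward_select(df, y, ForestParams(n_trees=20),
                                        max_features=2, seed=12)
        assert sel[0] in ("sep", "dup")
        assert len(sel) == 1

    def test_all_noise_selects_nothing_or_one(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.standard_normal((80, 5)),
                          columns=[f"n{i}" for i in range(5)])
        y = np.where(rng.random(80) < 0.5, "high", "low")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel, trace = forward_select(df, y, ForestParams(n_trees=20),
                                        max_features=5, min_gain=0.02,
                                        seed=13)
        assert len(sel) <= 1
        assert trace.loc[trace["round"] == 1, "auc"].max() < 0.75

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(14)
        df, y = separable_frame(rng, n=60, n_noise=3)
        kw = dict(params=ForestParams(n_trees=10), max_features=2, seed=14)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1, t1 = forward_select(df, y, **kw)
            s2, t2 = forward_select(df, y, **kw)
        assert s1 == s2
        pd.testing.assert_frame_equal(t1, t2)


class TestHyperparamSearch:
    def test_single_point_space_returned(self):
        rng = np.random.default_rng(15)
        df, y = separable_frame(rng, n=60)
        best, results = hyperparam_search(df, y, {"n_trees": [7]}, budget=3,
                                          seed=15)
        assert best.n_trees == 7
        assert len(results) == 1

    def test_zero_budget_returns_defaults(self):
        best, results = hyperparam_search(pd.DataFrame({"a": [1.0] * 30}),
                                          np.array(["low", "high"] * 15),
                                          {"n_trees": [5, 10]}, budget=0)
        assert best == ForestParams()

    def test_best_at_least_as_good_as_grid_oracle(self):
        rng = np.random.default_rng(16)
        df, y = separable_frame(rng, n=70, n_noise=2)
        space = {"n_trees": [5, 10, 20, 30, 40]}
        best, results = hyperparam_search(df, y, space, budget=5, seed=16)
        assert results["auc"].max() == results.set_index("n_trees").loc[
            best.n_trees, "auc"]

    def test_same_seed_same_result(self):
        rng = np.random.default_rng(17)
        df, y = separable_frame(rng, n=60)
        space = {"n_trees": [5, 10, 15], "min_leaf": [2, 5]}
        b1, _ = hyperparam_search(df, y, space, budget=4, seed=17)
        b2, _ = hyperparam_search(df, y, space, budget=4, seed=17)
        assert b1 == b2


class TestImportance:
    def test_unused_feature_scores_zero(self):
        rng = np.random.default_rng(18)
        df, y = separable_frame(rng, n=80, n_noise=0)
        df["constant"] = 1.0  # never splittable, never a surrogate
        forest = fit_forest(df, y, ForestParams(n_trees=10, mtry=2), seed=18)
        imp = feature_importance(forest)
        assert imp["constant"] == 0.0
        assert imp["sep"] > 0.0

    def test_stump_importance_equals_gini_decrease(self):
        rng = np.random.default_rng(19)
        df, y = separable_frame(rng, n=80, n_noise=0)
        forest = fit_forest(df, y, ForestParams(n_trees=1, min_leaf=2,
                                                use_surrogates=False), seed=19)
        tree = forest.trees[0]
        assert tree.left.is_leaf and tree.right.is_leaf
        imp = feature_importance(forest)
        assert imp["sep"] == pytest.approx(tree.gain)

    def test_informative_features_outrank_noise(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 120
            z = rng.standard_normal(n)
            y = np.where(z + rng.normal(0, 0.6, n) > 0, "high", "low")
            df = pd.DataFrame({"signal": z})
            for j in range(5):
                df[f"noise{j}"] = rng.standard_normal(n)
            forest = fit_forest(df, y, ForestParams(n_trees=30), seed=seed)
            imp = feature_importance(forest)
            if imp.idxmax() == "signal":
                hits += 1
        assert hits >= 9

    def test_removing_unused_feature_preserves_predictions(self):
        rng = np.random.default_rng(20)
        df, y = separable_frame(rng, n=70, n_noise=0)
        df["constant"] = 2.5
        f_with = fit_forest(df, y, ForestParams(n_trees=10, mtry=2,
                                                use_surrogates=False), seed=20)
        imp = feature_importance(f_with)
        assert imp["constant"] == 0.0
        # a constant column can never change any routing decision
        probe = df.copy()
        probe["constant"] = -99.0
        np.testing.assert_allclose(f_with.predict_proba(df),
                                   f_with.predict_proba(probe))
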