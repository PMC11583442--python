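"""Shapley attributions (exactness, additivity) and permutation importance."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from omixplain.explain import (
    export_explanations,
    permutation_importance_table,
    sampling_shapley,
    shap_values_forest,
    shap_values_sklearn_tree,
    shapley_explanations,
)


def _brute_force_tree_shap(tree, x, p):
    """Subset enumeration with the tree's cover-weighted conditional expectation."""
    t = tree.tree_
    vals = t.value.reshape(t.node_count, -1)

    def expvalue(S):
        def rec(node):
            if t.children_left[node] == -1:
                return vals[node]
            f = t.feature[node]
            if f in S:
                nxt = (
                    t.children_left[node]
                    if x[f] <= t.threshold[node]
                    else t.children_right[node]
                )
                return rec(nxt)
            l, r = t.children_left[node], t.children_right[node]
            wl = t.weighted_n_node_samples[l] / t.weighted_n_node_samples[node]
            return wl * rec(l) + (1 - wl) * rec(r)

        return rec(0)

    phis = np.zeros((p, vals.shape[1]))
    for j in range(p):
        others = [f for f in range(p) if f != j]
        for r in range(p):
            for S in combinations(others, r):
                w = factorial(len(S)) * factorial(p - len(S) - 1) / factorial(p)
                phis[j] += w * (expvalue(set(S) | {j}) - expvalue(set(S)))
    return phis


class TestTreeAttribution:
    def test_depth_one_stump_matches_two_player_game(self):
        # stump on feature 0: the hand computation over both orderings
        X = np.array([[0.0, 5.0]] * 6 + [[1.0, 5.0]] * 2)
        y = np.array([0.0] * 6 + [12.0] * 2)
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        x = np.array([1.0, 0.0])
        phi, base = shap_values_sklearn_tree(stump, x[None, :])
        # base = cover-weighted mean = 3; revealing feature 0 moves the
        # output to 12; feature 1 is never split on
        assert base[0] == pytest.approx(3.0)
        assert phi[0, 0, 0] == pytest.approx(9.0)
        assert phi[0, 1, 0] == pytest.approx(0.0)

    def test_matches_subset_enumeration_random_trees(self):
        rng = np.random.default_rng(0)
        for trial in range(6):
            n, p = 80, 4
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            tree = DecisionTreeRegressor(max_depth=5, random_state=trial).fit(X, y)
            xs = rng.normal(size=(2, p))
            phi, base = shap_values_sklearn_tree(tree, xs)
            for i in range(2):
                brute = _brute_force_tree_shap(tree, xs[i], p)
                np.testing.assert_allclose(phi[i], brute, atol=1e-10)

    def test_repeated_splits_on_same_feature_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 2))
        y = np.sin(3 * X[:, 0]) + X[:, 1]
        tree = DecisionTreeRegressor(max_depth=6, random_state=0).fit(X, y)
        xs = rng.normal(size=(3, 2))
        phi, base = shap_values_sklearn_tree(tree, xs)
        for i in range(3):
            brute = _brute_force_tree_shap(tree, xs[i], 2)
            np.testing.assert_allclose(phi[i], brute, atol=1e-10)

    def test_compiled_kernel_matches_pure_python_reference(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(200, 6))
        y = X[:, 0] * np.sin(X[:, 1]) + rng.normal(size=200)
        tree = DecisionTreeRegressor(max_depth=9, random_state=0).fit(X, y)
        xs = rng.normal(size=(10, 6))
        fast, base_f = shap_values_sklearn_tree(tree, xs, use_fast=True)
        slow, base_s = shap_values_sklearn_tree(tree, xs, use_fast=False)
        np.testing.assert_allclose(fast, slow, atol=1e-12)
        np.testing.assert_allclose(base_f, base_s)

    def test_forest_additivity_on_probability_scale(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=25, random_state=0).fit(X, y)
        xs = rng.normal(size=(8, 6))
        phi, base = shap_values_forest(rf, xs)
        np.testing.assert_allclose(
            base[None, :] + phi.sum(axis=1), rf.predict_proba(xs), atol=1e-6
        )

    def test_constant_model_all_attributions_zero(self):
        X = np.random.default_rng(3).normal(size=(30, 4))
        y = np.full(30, 7.5)
        tree = DecisionTreeRegressor(random_state=0).fit(X, y)
        phi, base = shap_values_sklearn_tree(tree, X[:5])
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)
        assert base[0] == pytest.approx(7.5)


class TestBoosterAttribution:
    def test_xgboost_additivity_to_margin(self):
        xgboost = pytest.importorskip("xgboost")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] > 0).astype(int)
        model = xgboost.XGBClassifier(
            n_estimators=20, max_depth=3, random_state=0
        ).fit(X, y)
        expl = shapley_explanations(
            model, pd.DataFrame(X[:10], columns=[f"f{j}" for j in range(5)]),
            "classification", class_names=["0", "1"],
        )
        total = sum(
            df.to_numpy().sum(axis=1) + expl.base_values[out]
            for out, df in expl.attributions.items()
        )
        margin = model.get_booster().predict(
            xgboost.DMatrix(X[:10]), output_margin=True
        )
        np.testing.assert_allclose(total, margin, atol=1e-4)

    def test_lightgbm_additivity_to_raw_score(self):
        lightgbm = pytest.importorskip("lightgbm")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 5))
        y = X[:, 0] * 2 + rng.normal(size=120) * 0.1
        model = lightgbm.LGBMRegressor(
            n_estimators=30, random_state=0, verbose=-1
        ).fit(X, y)
        expl = shapley_explanations(
            model, pd.DataFrame(X[:10], columns=[f"f{j}" for j in range(5)]),
            "regression",
        )
        df = expl.attributions["value"]
        total = df.to_numpy().sum(axis=1) + expl.base_values["value"]
        np.testing.assert_allclose(total, model.predict(X[:10]), atol=1e-6)


class TestSamplingAttribution:
    def test_additivity_by_construction(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 4))
        y = X @ np.array([2.0, -1.0, 0.0, 0.0]) + rng.normal(size=60) * 0.1
        model = KNeighborsRegressor(n_neighbors=5).fit(X, y)
        fn = lambda Z: model.predict(Z)[:, None]
        phi, base = sampling_shapley(fn, X[:6], X, n_permutations=10, seed=0)
        total = phi.sum(axis=1)[:, 0] + base[0]
        np.testing.assert_allclose(total, model.predict(X[:6]), atol=1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        y = X[:, 0]
        model = KNeighborsRegressor(n_neighbors=3).fit(X, y)
        fn = lambda Z: model.predict(Z)[:, None]
        a = sampling_shapley(fn, X[:4], X, n_permutations=8, seed=5)
        b = sampling_shapley(fn, X[:4], X, n_permutations=8, seed=5)
        np.testing.assert_array_equal(a[0], b[0])

    def test_irrelevant_feature_near_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 3))
        y = 3.0 * X[:, 0]
        model = KNeighborsRegressor(n_neighbors=3).fit(X, y)
        fn = lambda Z: model.predict(Z)[:, None]
        phi, _ = sampling_shapley(fn, X[:20], X, n_permutations=30, seed=0)
        mean_abs = np.abs(phi[:, :, 0]).mean(axis=0)
        assert mean_abs[0] > 5 * mean_abs[2]


    def test_adaboost_dispatches_to_sampling_with_exact_additivity(self):
        from sklearn.ensemble import AdaBoostClassifier

        rng = np.random.default_rng(15)
        X = pd.DataFrame(
            rng.normal(size=(80, 4)), columns=[f"f{j}" for j in range(4)]
        )
        y = np.where(X["f0"] + X["f1"] > 0, "hi", "lo")
        model = AdaBoostClassifier(n_estimators=10, random_state=0).fit(X.values, y)
        expl = shapley_explanations(
            model, X.iloc[:8], "classification",
            class_names=["hi", "lo"], background=X.values, seed=0,
        )
        totals = sum(
            df.to_numpy() for df in expl.attributions.values()
        ).sum(axis=1) + sum(expl.base_values.values())
        proba_sum = model.predict_proba(X.values[:8]).sum(axis=1)
        np.testing.assert_allclose(totals, proba_sum, atol=1e-10)


class TestPermutationImportance:
    def _fit(self, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(150, 5)), columns=[f"f{j}" for j in range(5)]
        )
        y = np.where(X["f0"] > 0, "pos", "neg")
        model = RandomForestClassifier(n_estimators=30, random_state=0).fit(X.values, y)
        return model, X, y

    def test_predictive_feature_dominates(self):
        model, X, y = self._fit()
        table = permutation_importance_table(model, X, y, "accuracy", repeats=5, seed=0)
        assert table.iloc[0]["feature"] == "f0"
        assert table.iloc[0]["importance_mean"] > 0.2

    def test_null_features_near_zero(self):
        model, X, y = self._fit()
        table = permutation_importance_table(model, X, y, "accuracy", repeats=5, seed=0)
        nulls = table[table["feature"] != "f0"]["importance_mean"]
        assert np.abs(nulls).max() < 0.1

    def test_deterministic_given_seed(self):
        model, X, y = self._fit()
        a = permutation_importance_table(model, X, y, "accuracy", repeats=3, seed=4)
        b = permutation_importance_table(model, X, y, "accuracy", repeats=3, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_importances_beat_null_quantile(self):
        rng = np.random.default_rng(9)
        n, p, informative = 150, 30, 4
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)]
        )
        y = np.where(X.iloc[:, :informative].sum(axis=1) > 0, "a", "b")
        model = RandomForestClassifier(n_estimators=50, random_state=0).fit(X.values, y)
        table = permutation_importance_table(model, X, y, "accuracy", repeats=5, seed=0)
        imp = table.set_index("feature")["importance_mean"]
        nulls = imp[[f"f{j}" for j in range(informative, p)]]
        cutoff = np.quantile(nulls, 0.95)
        assert all(imp[f"f{j}"] > cutoff for j in range(informative))


class TestExport:
    def _bundle(self, problem, n_outputs):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(
            rng.normal(size=(20, 4)),
            index=[f"S{i}" for i in range(20)],
            columns=[f"f{j}" for j in range(4)],
        )
        if problem == "classification":
            y = rng.choice([f"cls{i}" for i in range(n_outputs)], size=20)
            model = RandomForestClassifier(n_estimators=5, random_state=0).fit(
                X.values, y
            )
            classes = sorted(set(y))
        else:
            model = RandomForestRegressor(n_estimators=5, random_state=0).fit(
                X.values, rng.normal(size=20)
            )
            classes = None
        return shapley_explanations(model, X, problem, class_names=classes), X

    def test_one_shapley_csv_per_class(self, tmp_path):
        bundle, _ = self._bundle("classification", 3)
        files = export_explanations(bundle, "rf", tmp_path, "classification")
        shap_files = sorted(
            p.name for p in tmp_path.glob("shapley_values_all_rf_*.csv")
        )
        assert shap_files == [
            "shapley_values_all_rf_cls0.csv",
            "shapley_values_all_rf_cls1.csv",
            "shapley_values_all_rf_cls2.csv",
        ]

    def test_single_csv_for_regression_with_round_trip(self, tmp_path):
        bundle, _ = self._bundle("regression", 1)
        export_explanations(bundle, "rf", tmp_path, "regression")
        path = tmp_path / "shapley_values_all_rf.csv"
        assert path.exists()
        reread = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(
            reread.to_numpy(), bundle.attributions["value"].to_numpy()
        )

    def test_permutation_csv_name_template(self, tmp_path):
        bundle, X = self._bundle("classification", 2)
        bundle.permutation_importance = pd.DataFrame(
            {"feature": X.columns, "importance_mean": 0.0, "importance_sd": 0.0}
        )
        export_explanations(bundle, "my_model", tmp_path, "classification")
        assert (tmp_path / "permutimp_TopFeatures_info_my_model.csv").exists()

    def test_global_ranking_length_respects_top_n(self):
        bundle, _ = self._bundle("classification", 2)
        bundle.top_n = 2
        assert len(bundle.global_ranking()) == 2
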