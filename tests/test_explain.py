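"""F-score, cross-validation accounting, SHAP correctness, rule mining,
correlation clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from conftest import toy_table
from rheoprint._treeshap import (
    brute_shapley_tree,
    forest_shap_values,
    _tree_arrays,
    _tree_shap_one,
)
from rheoprint.explain import (
    ConfusionCounts,
    accumulate_shap,
    confusion_counts,
    correlate_cluster,
    cross_validate,
    f_score,
    global_importance,
    mine_split_rules,
    partial_dependence,
    shap_dependence,
    waterfall,
)


class TestFScore:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(10, 0, 0, 1.0), (8, 2, 2, 0.8), (0, 3, 5, 0.0), (5, 5, 0, 2 / 3)],
    )
    def test_closed_form(self, tp, fp, fn, expected):
        assert f_score(ConfusionCounts(tp, fp, fn, 0)) == pytest.approx(expected)

    def test_undefined_case_signaled(self):
        with pytest.raises(ValueError, match="undefined"):
            f_score(ConfusionCounts(0, 0, 0, 10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_confusion_counts_partition(self):
        y = [1, 1, 0, 0, 1, 0]
        p = [1, 0, 0, 1, 1, 0]
        c = confusion_counts(y, p)
        assert (c.TP, c.FP, c.FN, c.TN) == (2, 1, 1, 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_bounded(self, tp, fp, fn):
        if tp + fp + fn == 0:
            return
        assert 0.0 <= f_score(ConfusionCounts(tp, fp, fn, 0)) <= 1.0


class TestCrossValidate:
    def test_fold_accounting(self):
        """20 x 5 = 100 fold evaluations; every row in exactly one test fold
        per repeat; fold sizes differ by at most one."""
        table = toy_table(n=100, seed=0)
        cv = cross_validate(table, n_repeats=3, k=5, n_trees=20, seed=0,
                            compute_oob=False)
        assert len(cv.fold_scores) == 15
        assert cv.fold_scores.groupby("repeat").size().eq(5).all()

    def test_separable_table_perfect_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        table = pd.DataFrame(X, columns=["a", "b", "c"])
        table["printable"] = X[:, 0] > 0  # margin huge, fully separable
        cv = cross_validate(table, n_repeats=2, k=4, n_trees=50, seed=1,
                            compute_oob=False)
        assert cv.per_class["printable"]["mean"] == pytest.approx(1.0, abs=0.02)

    def test_statistics_consistent(self):
        table = toy_table(n=90, seed=1)
        cv = cross_validate(table, n_repeats=2, k=3, n_trees=30, seed=0,
                            compute_oob=True)
        for cls in cv.per_class.values():
            assert cls["min"] <= cls["mean"] <= cls["max"]
            assert 0.0 <= cls["min"] and cls["max"] <= 1.0
        assert 0.0 <= cv.oob_mean <= 1.0

    def test_k_exceeding_minority_rejected(self):
        table = toy_table(n=40, seed=2)
        table["printable"] = [True] * 3 + [False] * 37
        with pytest.raises(ValueError, match="minority"):
            cross_validate(table, n_repeats=1, k=5, n_trees=10)

    def test_label_permutation_null(self):
        """Permuting labels destroys the signal: mean printable F collapses
        toward the chance level of the prevalence."""
        table = toy_table(n=120, seed=3)
        rng = np.random.default_rng(0)
        perm = table.copy()
        scores = []
        for _ in range(5):
            perm["printable"] = rng.permutation(perm["printable"].to_numpy())
            if perm["printable"].sum() < 3:
                continue
            cv = cross_validate(perm, n_repeats=1, k=3, n_trees=30, seed=1,
                                compute_oob=False)
            scores.append(cv.per_class["printable"]["mean"])
        true_cv = cross_validate(table, n_repeats=1, k=3, n_trees=30, seed=1,
                                 compute_oob=False)
        assert np.mean(scores) < 0.6 < true_cv.per_class["printable"]["mean"]


class TestTreeShap:
    def test_depth2_matches_exhaustive_coalition_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            X = rng.integers(0, 2, size=(60, 3)).astype(float)
            y = (X[:, 0] + X[:, 1] * X[:, 2] + rng.random(60) * 0.5 > 1).astype(int)
            if len(np.unique(y)) < 2:
                continue
            tree = DecisionTreeClassifier(max_depth=2, random_state=trial).fit(X, y)
            arrays = _tree_arrays(tree)
            for i in range(4):
                phi = np.zeros(3)
                _tree_shap_one(*arrays[:6], X[i], phi, arrays[6])
                oracle = brute_shapley_tree(tree, X[i], 3)
                np.testing.assert_allclose(phi, oracle, atol=1e-12)

    def test_deep_tree_matches_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 4))
        y = (X[:, 0] * X[:, 1] + X[:, 2] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=6, random_state=0).fit(X, y)
        arrays = _tree_arrays(tree)
        for i in range(5):
            phi = np.zeros(4)
            _tree_shap_one(*arrays[:6], X[i], phi, arrays[6])
            np.testing.assert_allclose(phi, brute_shapley_tree(tree, X[i], 4), atol=1e-10)

    def test_constant_model_all_zero(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        rf = RandomForestClassifier(n_estimators=5, max_depth=1, random_state=0)
        rf.fit(X, np.zeros(40, dtype=int) + y * 0)  # single class -> no splits
        phi, base = forest_shap_values(rf, X[:5])
        np.testing.assert_allclose(phi, 0.0)
        assert base == pytest.approx(rf.predict_proba(X[:1])[0, -1])

    def test_forest_local_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 6))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0.3).astype(int)
        rf = RandomForestClassifier(n_estimators=60, random_state=0).fit(X, y)
        phi, base = forest_shap_values(rf, X)
        pred = rf.predict_proba(X)[:, -1]
        assert np.abs(base + phi.sum(axis=1) - pred).max() < 1e-6

    def test_duplicated_feature_symmetry(self):
        """Exchangeable duplicate features receive equal attributions up to
        forest sampling noise."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=300)
        X = np.column_stack([a, a, rng.normal(size=300)])
        y = (a > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=400, random_state=0).fit(X, y)
        phi, _ = forest_shap_values(rf, X[:50])
        m0, m1 = np.abs(phi[:, 0]).mean(), np.abs(phi[:, 1]).mean()
        assert abs(m0 - m1) / max(m0, m1) < 0.25


@pytest.fixture(scope="module")
def shap():
    table = toy_table(n=90, p=4, seed=4)
    return accumulate_shap(table, n_repeats=3, k=3, n_trees=40, seed=0), table


class TestShapAccumulation:

    def test_local_accuracy_per_fold_and_accumulated(self, shap):
        S, _ = shap
        assert S.max_local_error < 1e-6
        recon = S.base_per_obs + S.values.sum(axis=1)
        assert np.abs(recon - S.prediction).max() < 1e-6

    def test_every_observation_explained_each_repeat(self, shap):
        S, _ = shap
        assert (S.provenance >= 0).all().all()

    def test_global_importance_ordering(self, shap):
        S, _ = shap
        imp = global_importance(S)
        assert list(imp.index)[0] in ("x0", "x1")  # the informative pair
        assert (imp.values[:-1] >= imp.values[1:]).all()

    def test_importance_linearity(self, shap):
        S, _ = shap
        doubled = S.values.copy()
        doubled["x2"] *= 2.0
        S2 = type(S)(values=doubled, base_value=S.base_value,
                     base_per_obs=S.base_per_obs, prediction=S.prediction,
                     X=S.X, provenance=S.provenance,
                     max_local_error=S.max_local_error)
        assert global_importance(S2)["x2"] == pytest.approx(2 * global_importance(S)["x2"])

    def test_waterfall_reconstruction(self, shap):
        S, _ = shap
        obs = S.values.index[0]
        w = waterfall(S, obs)
        contrib = w["contribution"].to_numpy()
        assert (np.abs(contrib[:-1]) >= np.abs(contrib[1:])).all()
        assert w.attrs["base_value"] + contrib.sum() == pytest.approx(
            w.attrs["prediction"], abs=1e-6
        )

    def test_waterfall_unknown_observation(self, shap):
        S, _ = shap
        with pytest.raises(KeyError):
            waterfall(S, "nope")

    def test_dependence_override_honored(self, shap):
        S, _ = shap
        dep = shap_dependence(S, "x0", color_feature="x3")
        assert (dep["color_feature"] == "x3").all()
        assert len(dep) == len(S.values)
        with pytest.raises(KeyError):
            shap_dependence(S, "not_a_feature")


class TestPartialDependence:
    def test_ignored_feature_flat(self):
        table = toy_table(n=80, p=4, seed=5)
        X = table.drop(columns=["score", "printable"])
        y = table["printable"].astype(int)
        rf = RandomForestClassifier(n_estimators=30, random_state=0).fit(X.iloc[:, :2], y)

        class Wrap:
            def predict_proba(self, Z):
                return rf.predict_proba(Z.iloc[:, :2])

        pd_curve = partial_dependence(Wrap(), X, "x3", grid_points=8)
        assert pd_curve["mean_probability"].nunique() == 1

    def test_step_model_steps_at_threshold(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 200), "b": rng.normal(size=200)})

        class Step:
            def predict_proba(self, Z):
                p = (Z["a"].to_numpy() > 0.5).astype(float)
                return np.column_stack([1 - p, p])

        curve = partial_dependence(Step(), X, "a", grid_points=21)
        probs = curve["mean_probability"].to_numpy()
        assert set(np.round(probs, 6)) <= {0.0, 1.0}
        jump = curve["value"][np.flatnonzero(np.diff(probs))[0] + 1]
        assert abs(jump - 0.5) < 0.06


class TestSplitMining:
    def test_single_stump_catalog(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0]])
        y = np.array([0, 0, 1, 1])
        rf = RandomForestClassifier(n_estimators=1, max_depth=1, bootstrap=False,
                                    random_state=0).fit(X, y)
        cat = mine_split_rules(rf, ["A"])
        assert cat.n_nodes["A"] == 1
        assert 1.0 < cat.thresholds["A"][0] < 5.0

    def test_catalog_completeness(self, planted_forest):
        """Sum of per-feature node counts equals the forest's internal
        node count exactly."""
        rf, X, _ = planted_forest
        cat = mine_split_rules(rf, list(X.columns))
        internal = sum(
            int((est.tree_.children_left >= 0).sum()) for est in rf.estimators_
        )
        assert cat.total_nodes == internal
        assert sum(cat.n_nodes.values()) == internal
        assert all(len(cat.thresholds[f]) == cat.n_nodes[f] for f in cat.n_nodes)

    def test_unused_feature_empty(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=100), np.zeros(100)])
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=10, random_state=0).fit(X, y)
        cat = mine_split_rules(rf, ["used", "constant"])
        assert cat.n_nodes["constant"] == 0
        assert cat.summary().query("feature == 'constant'").empty

    def test_unfitted_forest_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            mine_split_rules(RandomForestClassifier())


class TestCorrelationClustering:
    def test_spearman_matches_rank_oracle(self):
        """Pairwise rho agrees with the explicit rank-correlation formula."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(5, 3)), columns=["a", "b", "c"])
        df["printable"] = [0, 1, 0, 1, 0]
        out = correlate_cluster(df, ["a", "b", "c"])
        for f1 in "abc":
            for f2 in "abc":
                r1 = rankdata(df[f1])
                r2 = rankdata(df[f2])
                oracle = np.corrcoef(r1, r2)[0, 1]
                assert out.rho.loc[f1, f2] == pytest.approx(oracle, abs=1e-12)

    def test_duplicated_feature_same_cluster(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["a_copy"] = df["a"]
        df["other"] = rng.normal(size=30)
        out = correlate_cluster(df, ["a", "a_copy", "other"])
        assert out.rho.loc["a", "a_copy"] == pytest.approx(1.0)
        assert out.clusters["a"] == out.clusters["a_copy"]

    def test_two_block_structure_recovered(self):
        rng = np.random.default_rng(9)
        n = 120
        u, v = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame(
            {f"u{i}": u + 0.3 * rng.normal(size=n) for i in range(3)}
            | {f"v{i}": v + 0.3 * rng.normal(size=n) for i in range(3)}
        )
        out = correlate_cluster(df, list(df.columns))
        ids_u = {out.clusters[f"u{i}"] for i in range(3)}
        ids_v = {out.clusters[f"v{i}"] for i in range(3)}
        assert len(ids_u) == 1 and len(ids_v) == 1 and ids_u != ids_v

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = correlate_cluster(df, ["a", "b", "flat"])
        assert out.dropped == ["flat"]
        assert "flat" not in out.rho.columns
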