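"""Feature table assembly, F ranking, VIF pruning and the classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import sleepfrag as sf
from sleepfrag.predict import (
    FEATURE_SCHEMA,
    TOP10_FEATURES,
    FRankSelector,
    SusceptibilityClassifier,
    VIFPruner,
    accuracy_vs_k,
    build_feature_table,
    cross_validated_accuracy,
    f_rank,
    pca_projection,
    vif_prune,
)

from oracles import anova_f_oracle, r2_two_predictors


def _toy_table(X: dict, labels) -> pd.DataFrame:
    table = pd.DataFrame(X)
    table.index = [f"m{i}" for i in range(len(table))]
    table.index.name = "animal"
    table["phenotype"] = labels
    return table


class TestBuildFeatureTable:
    def test_complete_animals_fixed_schema(self, small_cohort):
        table = build_feature_table(
            small_cohort.baseline_hypnograms(), small_cohort.labels())
        assert list(table.columns) == [*FEATURE_SCHEMA, "phenotype"]
        assert len(table) == 16
        assert set(table.phenotype) == {"SUSCEPTIBLE", "RESILIENT"}

    def test_top_named_features_present(self, small_cohort):
        table = build_feature_table(
            small_cohort.baseline_hypnograms(), small_cohort.labels())
        for feature in TOP10_FEATURES:
            assert feature in table.columns

    def test_input_order_invariance(self, small_cohort):
        hyps = small_cohort.baseline_hypnograms()
        labels = small_cohort.labels()
        a = build_feature_table(hyps, labels)
        reordered = dict(reversed(list(hyps.items())))
        b = build_feature_table(reordered, labels)
        pd.testing.assert_frame_equal(a, b)

    def test_excluded_animals_dropped(self, small_cohort):
        hyps = small_cohort.baseline_hypnograms()
        labels = dict(small_cohort.labels())
        victim = next(iter(labels))
        labels[victim] = "EXCLUDED"
        table = build_feature_table(hyps, labels)
        assert victim not in table.index
        assert len(table) == 15

    def test_animal_missing_a_phase_dropped(self, small_cohort):
        hyps = dict(small_cohort.baseline_hypnograms())
        victim = next(iter(hyps))
        light_only = sf.Hypnogram(hyps[victim].states[: 6 * 720])
        hyps[victim] = light_only
        table = build_feature_table(hyps, small_cohort.labels())
        assert victim not in table.index


class TestFRank:
    def test_hand_anova_example(self):
        table = _toy_table(
            {"f": [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]},
            ["A"] * 3 + ["B"] * 3,
        )
        out = f_rank(table, k=1)
        assert out.loc["f", "F"] == pytest.approx(6.0)
        assert out.loc["f", "F"] == pytest.approx(
            anova_f_oracle([1, 2, 3], [3, 4, 5]))

    def test_constant_feature_ranked_last_separating_first(self):
        table = _toy_table(
            {
                "const": [7.0] * 4,
                "perfect": [0.0, 0.0, 1.0, 1.0],
                "noisy": [0.1, 0.5, 0.4, 0.9],
            },
            ["A", "A", "B", "B"],
        )
        sel = FRankSelector(k=3).fit(
            table.drop(columns="phenotype"), table.phenotype)
        assert sel.scores_["const"] == 0.0
        assert np.isinf(sel.scores_["perfect"])
        assert sel.ranking_[0] == "perfect"
        assert sel.ranking_[-1] == "const"

    def test_affine_rescaling_invariance(self, rng):
        X = rng.normal(size=(12, 4))
        y = ["A"] * 6 + ["B"] * 6
        a = FRankSelector().fit(pd.DataFrame(X), y).scores_
        b = FRankSelector().fit(pd.DataFrame(X * 3.7 + 11.0), y).scores_
        assert np.allclose(a.values, b.values)

    def test_small_class_rejected(self):
        table = _toy_table({"f": [1.0, 2.0, 3.0]}, ["A", "A", "B"])
        with pytest.raises(ValueError, match=">= 2"):
            f_rank(table)

    def test_tie_break_is_lexical(self):
        table = _toy_table(
            {"b": [1.0, 1.0, 2.0, 2.0], "a": [1.0, 1.0, 2.0, 2.0]},
            ["A", "A", "B", "B"],
        )
        sel = FRankSelector().fit(table.drop(columns="phenotype"), table.phenotype)
        assert sel.ranking_ == ["a", "b"]


class TestVIFPrune:
    def test_orthogonal_features_untouched(self):
        # zero-mean mutually orthogonal columns (Hadamard design)
        X = pd.DataFrame(
            {
                "h1": [1.0, -1.0, 1.0, -1.0],
                "h2": [1.0, 1.0, -1.0, -1.0],
                "h3": [1.0, -1.0, -1.0, 1.0],
            }
        )
        pruner = VIFPruner(threshold=35.0).fit(X)
        assert pruner.retained_ == ["h1", "h2", "h3"]
        assert np.allclose(pruner.vifs_.values, 1.0)
        assert pruner.trace_.empty

    def test_exact_duplicate_removed_first_with_infinite_vif(self, rng):
        base = rng.normal(size=8)
        X = pd.DataFrame({
            "orig": base,
            "copy": base.copy(),
            "other": rng.normal(size=8),
        })
        pruner = VIFPruner(threshold=35.0).fit(X)
        assert pruner.trace_.iloc[0]["vif"] == np.inf
        # lexical tie-break between the two infinite-VIF duplicates
        assert pruner.trace_.iloc[0]["feature"] == "copy"
        assert pruner.retained_ == ["orig", "other"]

    def test_near_collinear_triple_matches_hand_oracle(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        x3 = x1 + x2 + rng.normal(scale=0.05, size=30)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        # hand oracle, step 1: VIF of each from closed-form multiple R^2
        vifs = {
            "x1": 1.0 / (1.0 - r2_two_predictors(x1, x2, x3)),
            "x2": 1.0 / (1.0 - r2_two_predictors(x2, x1, x3)),
            "x3": 1.0 / (1.0 - r2_two_predictors(x3, x1, x2)),
        }
        worst = max(sorted(vifs), key=lambda k: vifs[k])
        assert vifs[worst] > 35.0
        # after removing the worst, the survivors' pairwise VIFs
        survivors = [k for k in ("x1", "x2", "x3") if k != worst]
        r = np.corrcoef(X[survivors[0]], X[survivors[1]])[0, 1]
        assert 1.0 / (1.0 - r**2) <= 35.0
        pruner = VIFPruner(threshold=35.0).fit(X)
        assert list(pruner.trace_.feature) == [worst]
        assert pruner.trace_.iloc[0]["vif"] == pytest.approx(
            vifs[worst], rel=1e-9)
        assert pruner.retained_ == survivors

    def test_terminates_with_all_vifs_below_threshold(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)),
                         columns=list("abcdef"))
        X["g"] = X["a"] + X["b"]
        X["h"] = X["a"] - X["c"] + 0.01 * rng.normal(size=20)
        pruner = VIFPruner(threshold=5.0).fit(X)
        assert len(pruner.trace_) <= X.shape[1] - 1
        assert pruner.vifs_.max() <= 5.0

    def test_infeasible_threshold_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError, match="eliminates every feature"):
            VIFPruner(threshold=0.5).fit(X)


class TestClassifier:
    def test_perfectly_separating_feature_scores_one(self):
        table = _toy_table(
            {"f": [0.0, 0.1, 0.2, 0.3, 5.0, 5.1, 5.2, 5.3]},
            ["A"] * 4 + ["B"] * 4,
        )
        res = cross_validated_accuracy(table, ["f"], n_repeats=50, seed=1)
        assert res.mean_accuracy == 1.0

    def test_bitwise_reproducibility(self, small_cohort):
        table = build_feature_table(
            small_cohort.baseline_hypnograms(), small_cohort.labels())
        feats = list(TOP10_FEATURES[:3])
        a = cross_validated_accuracy(table, feats, n_repeats=25, seed=7)
        b = cross_validated_accuracy(table, feats, n_repeats=25, seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert all(np.array_equal(x, y) for x, y in zip(a.coefs, b.coefs))

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(31)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = np.array(["A", "B"] * (n // 2))
        rng.shuffle(y)
        table = X.copy()
        table["phenotype"] = y
        res = cross_validated_accuracy(
            table, list(X.columns), n_repeats=200, seed=3)
        assert 0.4 <= res.mean_accuracy <= 0.6

    def test_duplicating_animals_keeps_accuracy(self):
        rng = np.random.default_rng(8)
        X = {"f": np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10)])}
        table = _toy_table(X, ["A"] * 10 + ["B"] * 10)
        doubled = pd.concat([table, table])
        doubled.index = [f"m{i}" for i in range(len(doubled))]
        a = cross_validated_accuracy(table, ["f"], n_repeats=100, seed=0)
        b = cross_validated_accuracy(doubled, ["f"], n_repeats=100, seed=0)
        assert abs(a.mean_accuracy - b.mean_accuracy) < 0.1

    def test_sklearn_estimator_contract(self):
        est = SusceptibilityClassifier(C=0.5)
        assert est.get_params()["C"] == 0.5
        cloned = clone(est).set_params(C=2.0)
        assert cloned.get_params()["C"] == 2.0
        X = pd.DataFrame({"f": [0.0, 0.0, 1.0, 1.0]})
        y = np.array(["A", "A", "B", "B"])
        est.fit(X, y)
        assert set(est.predict(X)) <= {"A", "B"}
        assert est.coef_.shape == (1, 1)
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestAccuracyVsK:
    def test_k1_consistent_with_single_feature_run(self, small_cohort):
        table = build_feature_table(
            small_cohort.baseline_hypnograms(), small_cohort.labels())
        feats = list(TOP10_FEATURES[:3])
        curve = accuracy_vs_k(table, feats, n_repeats=25, seed=5)
        single = cross_validated_accuracy(
            table, feats[:1], n_repeats=25, seed=5)
        assert curve.loc[1] == single.mean_accuracy

    def test_informative_features_give_nondecreasing_curve(self):
        rng = np.random.default_rng(17)
        n = 60
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        shift = (y == "B").astype(float)
        X = pd.DataFrame(
            {f"f{i}": rng.normal(size=n) + 1.2 * shift for i in range(4)}
        )
        table = X.copy()
        table["phenotype"] = y
        curve = accuracy_vs_k(table, list(X.columns), n_repeats=100, seed=2)
        assert np.all(np.diff(curve.values) >= -0.03)

    def test_noise_features_at_small_n_degrade_accuracy(self):
        rng = np.random.default_rng(23)
        n = 16
        y = np.array(["A"] * 8 + ["B"] * 8)
        X = {"signal": np.where(y == "B", 1.6, 0.0) + rng.normal(0, 0.8, n)}
        for i in range(4):
            X[f"noise{i}"] = rng.normal(size=n)
        table = _toy_table(X, y)
        curve = accuracy_vs_k(
            table, ["signal", "noise0", "noise1", "noise2", "noise3"],
            n_repeats=200, seed=4)
        assert curve.iloc[-1] <= curve.iloc[0] + 0.02


class TestPCAProjection:
    def test_identical_animals_identical_coordinates(self):
        table = _toy_table(
            {"a": [1.0, 1.0, 3.0, 4.0], "b": [2.0, 2.0, 5.0, 1.0]},
            ["A", "A", "B", "B"],
        )
        coords, _ = pca_projection(table, ["a", "b"])
        assert np.allclose(coords.iloc[0], coords.iloc[1])

    def test_zero_variance_column_dropped(self):
        table = _toy_table(
            {"a": [1.0, 2.0, 3.0, 4.0], "z": [5.0] * 4},
            ["A", "A", "B", "B"],
        )
        coords, ratios = pca_projection(table, ["a", "z"], n_components=2)
        # 1-D projection equals the standardized surviving feature
        a = table["a"].to_numpy()
        z = (a - a.mean()) / a.std()
        assert np.allclose(coords["PC1"].to_numpy(), z)
        assert ratios == pytest.approx([1.0])

    def test_variance_fractions_match_eigendecomposition(self):
        M = np.array(
            [[1.0, 2.0, 0.5],
             [2.0, 1.0, 0.0],
             [3.0, 4.0, 1.5],
             [4.0, 3.0, 2.0]]
        )
        table = _toy_table(
            {"a": M[:, 0], "b": M[:, 1], "c": M[:, 2]},
            ["A", "A", "B", "B"],
        )
        _, ratios = pca_projection(table, ["a", "b", "c"], n_components=3)
        Z = (M - M.mean(axis=0)) / M.std(axis=0)
        eig = np.linalg.eigvalsh(Z.T @ Z)[::-1]
        assert np.allclose(ratios, eig / eig.sum(), atol=1e-9)


class TestEndToEndRecovery:
    def test_fragmentation_presets_are_recoverable(self, small_cohort):
        """Susceptible vs resilient cohorts differing in NREM
        fragmentation are separable from pre-stress sleep features."""
        table = build_feature_table(
            small_cohort.baseline_hypnograms(), small_cohort.labels())
        ranking = f_rank(table, k=10)
        retained, _ = vif_prune(table, features=list(ranking.index),
                                threshold=35.0)
        ranked = [f for f in ranking.index if f in retained]
        curve = accuracy_vs_k(table, ranked, k_max=min(5, len(ranked)),
                              n_repeats=200, seed=0)
        assert curve.max() >= 0.8
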