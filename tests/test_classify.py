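"""MFCC baseline, feature selection, grouped evaluation and metrics."""

import numpy as np
import pandas as pd
import pytest

from spectromesh.classify import (
    EvalProtocol,
    FeatureTable,
    _class_weights,
    combine_and_select,
    evaluate,
    grouped_split,
    metrics_from_counts,
    mfcc_feature_names,
    mfcc_features,
    rank_features,
    trajectory_statistics,
)
from spectromesh.preprocess import Signal


def make_table(X, labels, groups, prefix="f"):
    n, p = X.shape
    return FeatureTable.from_arrays(
        ids=[f"r{i}" for i in range(n)],
        groups=groups,
        labels=labels,
        X=X,
        feature_names=[f"{prefix}{j}" for j in range(p)],
    )


def blobs_table(rng, n_per_class=40, n_groups=8, gap=6.0, p=4):
    """Two widely separated Gaussian blobs with group structure."""
    X, labels, groups = [], [], []
    for c, name in enumerate(["a", "b"]):
        center = np.full(p, gap * c)
        X.append(center + rng.standard_normal((n_per_class, p)))
        labels += [name] * n_per_class
        groups += [f"{name}_g{i % n_groups}" for i in range(n_per_class)]
    return make_table(np.vstack(X), labels, groups)


class TestTrajectoryStatistics:
    def test_constant_trajectory(self):
        stats = trajectory_statistics(np.full((1, 10), 2.5))
        np.testing.assert_allclose(stats, [2.5, 0.0, 2.5, 2.5, 0.0, 0.0])

    def test_alternating_trajectory_hand_values(self):
        stats = trajectory_statistics(np.array([[0.0, 1.0, 0.0, 1.0]]))
        # mean .5, std .5, min 0, max 1, |diff| = (1,1,1) -> mean 1, std 0
        np.testing.assert_allclose(stats, [0.5, 0.5, 0.0, 1.0, 1.0, 0.0])

    def test_row_major_concatenation(self):
        stats = trajectory_statistics(np.array([[1.0, 1.0], [0.0, 2.0]]))
        assert stats.shape == (12,)
        np.testing.assert_allclose(stats[:6], [1, 0, 1, 1, 0, 0])


class TestMfccFeatures:
    def test_always_72_finite_features(self, tone_signal):
        feats = mfcc_features(tone_signal)
        assert feats.shape == (72,)
        assert np.all(np.isfinite(feats))
        assert len(mfcc_feature_names()) == 72

    def test_feature_names_coefficient_major(self):
        names = mfcc_feature_names()
        assert names[0] == "mfcc1_mean"
        assert names[5] == "mfcc1_absdiff_std"
        assert names[6] == "mfcc2_mean"

    def test_too_short_signal_rejected(self):
        sig = Signal(samples=np.zeros(50), rate=4000.0, id="x", group="g")
        with pytest.raises(ValueError, match="too short"):
            mfcc_features(sig)

    def test_distinct_signals_get_distinct_features(self, rng):
        rate = 4000.0
        t = np.arange(4000) / rate
        tone = Signal(samples=np.sin(2 * np.pi * 300 * t), rate=rate, id="a", group="g")
        noise = Signal(samples=rng.standard_normal(4000), rate=rate, id="b", group="g")
        assert not np.allclose(mfcc_features(tone), mfcc_features(noise), atol=0.1)


class TestMetrics:
    def test_hand_computed_confusion_values(self):
        m = metrics_from_counts(tp=50, tn=30, fp=10, fn=10)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(5 / 6)
        assert m["jaccard"] == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        m = metrics_from_counts(tp=7, tn=13, fp=0, fn=0)
        assert m["accuracy"] == m["recall"] == m["jaccard"] == 1.0

    def test_jaccard_never_exceeds_accuracy(self):
        for tp in range(5):
            for tn in range(5):
                for fp in range(5):
                    for fn in range(5):
                        if tp + tn + fp + fn == 0:
                            continue
                        m = metrics_from_counts(tp, tn, fp, fn)
                        assert m["jaccard"] <= m["accuracy"] + 1e-12


class TestCombineAndSelect:
    def make_pair(self, rng, n=30):
        groups = [f"g{i % 5}" for i in range(n)]
        labels = ["a" if i % 2 else "b" for i in range(n)]
        d = make_table(rng.standard_normal((n, 16)), labels, groups, prefix="d")
        m = make_table(rng.standard_normal((n, 72)), labels, groups, prefix="m")
        return d, m

    def test_identity_selection_at_full_width(self, rng):
        d, m = self.make_pair(rng)
        out = combine_and_select(d, m, k=88, seed=0)
        assert len(out.feature_names) == 88
        assert out.feature_names[:16] == [f"d{j}" for j in range(16)]

    def test_selection_keeps_top_k(self, rng):
        d, m = self.make_pair(rng)
        out = combine_and_select(d, m, k=45, seed=0)
        assert len(out.feature_names) == 45
        assert len(out) == len(d)

    def test_label_copy_feature_survives_selection(self, rng):
        d, m = self.make_pair(rng, n=40)
        frame = d.frame.copy()
        frame["d0"] = (frame["label"] == "a").astype(float)  # perfect feature
        d = FeatureTable(frame)
        out = combine_and_select(d, m, k=5, seed=0)
        assert "d0" in out.feature_names

    def test_selection_reproducible_under_seed(self, rng):
        d, m = self.make_pair(rng)
        a = combine_and_select(d, m, k=20, seed=3).feature_names
        b = combine_and_select(d, m, k=20, seed=3).feature_names
        assert a == b

    def test_mismatched_ids_rejected(self, rng):
        d, m = self.make_pair(rng)
        shifted = m.frame.copy()
        shifted["id"] = ["x" + i for i in shifted["id"]]
        with pytest.raises(ValueError, match="same ids"):
            combine_and_select(d, FeatureTable(shifted), k=10, seed=0)


class TestEvaluate:
    def test_grouped_split_is_disjoint(self, rng):
        table = blobs_table(rng)
        reports = evaluate(table, EvalProtocol(models=("rf",), n_search_iter=0))
        rep = reports["rf"]
        assert set(rep.train_groups).isdisjoint(rep.test_groups)
        assert set(rep.train_groups) | set(rep.test_groups) == set(table.groups)

    def test_separable_classes_classified_perfectly(self, rng):
        table = blobs_table(rng, gap=8.0)
        rep = evaluate(table, EvalProtocol(models=("rf",), n_search_iter=0, seed=0))["rf"]
        assert rep.accuracy == 1.0
        assert rep.auroc == 1.0
        assert rep.recall == 1.0 and rep.jaccard == 1.0

    def test_counts_are_consistent(self, rng):
        table = blobs_table(rng, gap=1.0)
        rep = evaluate(table, EvalProtocol(models=("rf",), n_search_iter=0))["rf"]
        n_test = sum(g in set(rep.test_groups) for g in table.groups)
        for c in rep.counts.values():
            assert c["TP"] + c["TN"] + c["FP"] + c["FN"] == n_test

    def test_hyperparameter_search_runs_grouped(self, rng):
        table = blobs_table(rng, gap=8.0, n_per_class=30, n_groups=6)
        rep = evaluate(
            table, EvalProtocol(models=("lr",), n_search_iter=3, seed=1)
        )["lr"]
        assert rep.best_params  # a parameter choice was recorded
        assert 0.0 <= rep.auroc <= 1.0

    def test_single_group_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        groups = ["ga"] * 5 + [f"gb{i}" for i in range(5)]
        with pytest.raises(ValueError, match="single group"):
            evaluate(make_table(X, labels, groups))

    def test_multiclass_reports_macro_metrics(self, rng):
        X, labels, groups = [], [], []
        for c, name in enumerate(["a", "b", "c"]):
            X.append(np.full((20, 3), 5.0 * c) + rng.standard_normal((20, 3)))
            labels += [name] * 20
            groups += [f"{name}{i % 5}" for i in range(20)]
        table = make_table(np.vstack(X), labels, groups)
        rep = evaluate(table, EvalProtocol(models=("rf",), n_search_iter=0))["rf"]
        assert set(rep.per_class) == {"a", "b", "c"}
        assert rep.accuracy == pytest.approx(1.0)

    def test_class_weights_inverse_to_frequency(self):
        w = _class_weights(np.array(["a"] * 30 + ["b"] * 10))
        assert w["b"] / w["a"] == pytest.approx(3.0)

    @pytest.mark.parametrize("model", ["knn", "adaboost", "xgboost", "svm"])
    def test_other_classifiers_run(self, rng, model):
        table = blobs_table(rng, gap=8.0, n_per_class=20, n_groups=5)
        rep = evaluate(table, EvalProtocol(models=(model,), n_search_iter=0))[model]
        assert rep.accuracy >= 0.9


class TestRankFeatures:
    def make_ranking_table(self, rng, n=60):
        X = rng.standard_normal((n, 5))
        labels = ["a" if i % 2 else "b" for i in range(n)]
        X[:, 2] = [1.0 if l == "a" else 0.0 for l in labels]  # label copy
        X[:, 4] = 7.0  # constant
        groups = [f"g{i % 6}" for i in range(n)]
        return make_table(X, labels, groups)

    def test_label_copy_ranks_first_constant_last(self, rng):
        table = self.make_ranking_table(rng)
        ranking = rank_features(table, "rf_importance", seed=0)
        assert ranking.iloc[0]["feature"] == "f2"
        assert ranking.iloc[-1]["feature"] == "f4"
        assert ranking.iloc[-1]["score"] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_backend_agrees_on_top_feature(self, rng):
        table = self.make_ranking_table(rng)
        ranking = rank_features(table, "permutation", seed=0)
        assert ranking.iloc[0]["feature"] == "f2"

    def test_deterministic_under_seed(self, rng):
        table = self.make_ranking_table(rng)
        a = rank_features(table, "rf_importance", seed=5)
        b = rank_features(table, "rf_importance", seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown ranking"):
            rank_features(self.make_ranking_table(rng), "shapely", seed=0)


class TestFeatureTable:
    def test_missing_values_rejected(self):
        df = pd.DataFrame(
            {"id": ["a"], "group": ["g"], "label": ["x"], "f0": [np.nan]}
        )
        with pytest.raises(ValueError, match="missing"):
            FeatureTable(df)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            {"id": ["a", "a"], "group": ["g", "g"], "label": ["x", "y"], "f0": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="unique"):
            FeatureTable(df)
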