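"""Feature fusion, class weighting, tree/forest training, LOO CV, metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import angiomoa as am
from conftest import tiny_config

P, I = am.PROMOTE, am.INHIBIT


def _blocks(n=12, n_tp=4, n_deg=3, seed=0):
    r = np.random.default_rng(seed)
    idx = [f"c{i}" for i in range(n)]
    tp = pd.DataFrame(r.integers(0, 2, size=(n, n_tp)), index=idx,
                      columns=[f"t{j}" for j in range(n_tp)])
    deg = pd.DataFrame(r.integers(0, 2, size=(n, n_deg)), index=idx,
                       columns=[f"g{j}" for j in range(n_deg)])
    labels = pd.Series([P, I] * (n // 2), index=idx)
    return tp, deg, labels


class TestFuseFeatures:
    def test_both_concatenates_with_prefixes(self):
        tp, deg, _ = _blocks()
        fm = am.fuse_features(tp, deg, "both")
        assert fm.values.shape[1] == tp.shape[1] + deg.shape[1]
        assert all(c.startswith(("TP:", "DEG:")) for c in fm.values.columns)

    def test_tp_only_is_identity_up_to_prefix(self):
        tp, deg, _ = _blocks()
        fm = am.fuse_features(tp, deg, "TP_only")
        assert fm.values.columns.tolist() == [f"TP:{c}" for c in tp.columns]
        assert (fm.values.to_numpy() == tp.to_numpy()).all()

    def test_zero_deg_row_padded(self):
        tp, deg, _ = _blocks()
        deg.loc["c0"] = 0
        fm = am.fuse_features(tp, deg, "both")
        row = fm.values.loc["c0"]
        assert (row[[c for c in fm.values.columns if c.startswith("DEG:")]] == 0).all()
        assert (row[[f"TP:{c}" for c in tp.columns]].to_numpy()
                == tp.loc["c0"].to_numpy()).all()

    def test_missing_modality_compounds_excluded(self, caplog):
        tp, deg, _ = _blocks()
        with caplog.at_level("INFO", logger="angiomoa.classifier"):
            fm = am.fuse_features(tp, deg.drop(index=["c3"]), "both")
        assert "c3" not in fm.values.index

    def test_empty_intersection_rejected(self):
        tp, deg, _ = _blocks()
        deg.index = [f"z{i}" for i in range(len(deg))]
        with pytest.raises(ValueError, match="no compound"):
            am.fuse_features(tp, deg, "both")


class TestClassWeights:
    def test_study_imbalance_weights(self):
        labels = pd.Series([P] * 19 + [I] * 32)
        weights, per_sample = am.class_weights(labels)
        assert weights[P] == pytest.approx(51 / 38)
        assert weights[I] == pytest.approx(51 / 64)
        assert per_sample.sum() == pytest.approx(51)  # conservation

    def test_equal_classes_unit_weights(self):
        weights, _ = am.class_weights(pd.Series([P, P, I, I]))
        assert weights[P] == weights[I] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            am.class_weights(pd.Series([P, P, P]))


def _separable(n=16):
    idx = [f"c{i}" for i in range(n)]
    labels = pd.Series([P] * (n // 2) + [I] * (n // 2), index=idx)
    X = pd.DataFrame({"split": (labels == P).astype(int),
                      "noise": ([0, 1] * n)[:n]}, index=idx)
    return X, labels


class TestTree:
    def test_perfect_feature_gives_depth_one_pure_leaves(self):
        X, labels = _separable()
        model, text, dot = am.train_tree(X, labels, am.ModelConfig(seed=1))
        assert model.get_depth() == 1
        assert "entropy=0.000" in text
        assert "split" in text.splitlines()[0]

    def test_balanced_root_entropy_one_bit(self):
        X, labels = _separable()
        model, text, _ = am.train_tree(X, labels, am.ModelConfig(seed=1))
        assert "entropy=1.000" in text.splitlines()[0]

    def test_constant_features_root_only(self, caplog):
        idx = [f"c{i}" for i in range(8)]
        X = pd.DataFrame({"f": [1] * 8}, index=idx)
        labels = pd.Series([P, I] * 4, index=idx)
        with caplog.at_level("WARNING", logger="angiomoa.classifier"):
            model, text, _ = am.train_tree(X, labels, am.ModelConfig(seed=1))
        assert model.get_depth() == 0

    def test_root_feature_recovers_planted_signal(self):
        hits, runs = 0, 20
        for s in range(runs):
            r = np.random.default_rng(s)
            n = 30
            idx = [f"c{i}" for i in range(n)]
            labels = pd.Series([P] * 15 + [I] * 15, index=idx)
            X = pd.DataFrame(r.integers(0, 2, size=(n, 10)), index=idx,
                             columns=[f"f{j}" for j in range(10)])
            planted = ((labels == P).astype(int).to_numpy()
                       ^ (r.random(n) < 0.05).astype(int))
            X["planted"] = planted
            _, text, _ = am.train_tree(X, labels, am.ModelConfig(seed=s))
            hits += int("planted" in text.splitlines()[0])
        assert hits / runs >= 0.9


class TestForest:
    def test_deterministic_given_seed(self):
        X, labels = _separable()
        cfg = am.ModelConfig(forest_n_trees=50, seed=9)
        p1 = am.promoter_probability(am.train_forest(X, labels, cfg), X)
        p2 = am.promoter_probability(am.train_forest(X, labels, cfg), X)
        assert (p1 == p2).all()

    def test_probabilities_valid_and_confident_on_separable(self):
        X, labels = _separable()
        model = am.train_forest(X, labels, am.ModelConfig(forest_n_trees=100, seed=2))
        proba = model.predict_proba(X.to_numpy())
        assert np.allclose(proba.sum(axis=1), 1.0)
        p = am.promoter_probability(model, X)
        assert (p[labels == P] > 0.9).all()
        assert (p[labels == I] < 0.1).all()


class TestMetrics:
    def test_four_sample_worked_example(self):
        labels = pd.Series([P, P, I, I], index=list("abcd"))
        probs = pd.Series([0.9, 0.3, 0.2, 0.6], index=list("abcd"))
        m = am.compute_metrics(labels, probs, threshold=0.5)
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(0.5)
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["roc_auc"] == pytest.approx(0.75)

    def test_all_correct(self):
        labels = pd.Series([P, I], index=list("ab"))
        m = am.compute_metrics(labels, pd.Series([0.9, 0.1], index=list("ab")), 0.5)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (1.0, 1.0, 1.0)

    def test_all_called_promoter(self):
        labels = pd.Series([P, I, I], index=list("abc"))
        m = am.compute_metrics(labels, pd.Series([0.9, 0.8, 0.7], index=list("abc")), 0.5)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0

    def test_empty_class_gives_nan_not_zero(self):
        assert math.isnan(am.metrics_from_confusion(0, 0, 3, 1)["sensitivity"])

    def test_concordance_auc_matches_trapezoidal(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert am.concordance_auc(y, s) == pytest.approx(
                roc_auc_score(y, s), abs=1e-10)


class TestLOOCV:
    def test_perfectly_separable_planted_data(self):
        X, labels = _separable(12)
        rep = am.loo_cv(X, labels, am.ModelConfig(forest_n_trees=50, seed=3))
        assert rep.metrics["roc_auc"] == 1.0
        assert rep.metrics["sensitivity"] == 1.0
        assert rep.metrics["specificity"] == 1.0
        assert rep.metrics["accuracy"] == 1.0

    def test_confusion_counts_sum_to_n(self):
        X, labels = _separable(10)
        rep = am.loo_cv(X, labels, am.ModelConfig(forest_n_trees=20, seed=3))
        m = rep.metrics
        assert m["tp"] + m["fn"] + m["tn"] + m["fp"] == len(labels)

    def test_too_few_compounds_rejected(self):
        X, labels = _separable(4)
        with pytest.raises(ValueError):
            am.loo_cv(X.iloc[:2], labels.iloc[:2], am.ModelConfig(forest_n_trees=5))


class TestCalibrateThreshold:
    def _probs(self):
        labels = pd.Series([P, P, P, I, I, I], index=list("abcdef"))
        probs = pd.Series([0.9, 0.6, 0.3, 0.5, 0.2, 0.1], index=list("abcdef"))
        return probs, labels

    def test_boundary_thresholds(self):
        probs, labels = self._probs()
        curve, op = am.calibrate_threshold(probs, labels, grid=[0.0, 0.5, 1.01])
        low = curve[curve.threshold == 0.0].iloc[0]
        assert (low["sensitivity"], low["specificity"]) == (1.0, 0.0)
        high = curve[curve.threshold == 1.01].iloc[0]
        assert (high["sensitivity"], high["n_called_promoter"]) == (0.0, 0)
        assert op == 0.4  # configured value never silently overridden

    def test_called_count_monotone_nonincreasing(self, rng):
        probs = pd.Series(rng.random(40), index=[f"c{i}" for i in range(40)])
        labels = pd.Series([P, I] * 20, index=probs.index)
        curve, _ = am.calibrate_threshold(probs, labels)
        assert (np.diff(curve["n_called_promoter"]) <= 0).all()

    def test_degenerate_grid_rejected(self):
        probs, labels = self._probs()
        with pytest.raises(ValueError, match="grid"):
            am.calibrate_threshold(probs, labels, grid=[0.5])


class TestGiniSelection:
    def test_single_informative_feature_ranks_first(self):
        hits, runs = 0, 20
        for s in range(runs):
            r = np.random.default_rng(1000 + s)
            n = 40
            idx = [f"c{i}" for i in range(n)]
            labels = pd.Series([P] * 20 + [I] * 20, index=idx)
            X = pd.DataFrame(r.integers(0, 2, size=(n, 15)), index=idx,
                             columns=[f"f{j}" for j in range(15)])
            X["signal"] = (labels == P).astype(int)
            forest = am.train_forest(X, labels,
                                     am.ModelConfig(forest_n_trees=100, seed=s))
            top = am.gini_top_features(forest, list(X.columns), k=5)
            hits += int(top["feature"].iloc[0] == "signal")
        assert hits / runs >= 0.95

    def test_importances_sum_to_one(self):
        X, labels = _separable()
        forest = am.train_forest(X, labels, am.ModelConfig(forest_n_trees=50, seed=4))
        assert forest.feature_importances_.sum() == pytest.approx(1.0)

    def test_k_equal_width_identity(self):
        X, labels = _separable()
        forest = am.train_forest(X, labels, am.ModelConfig(forest_n_trees=20, seed=4))
        top = am.gini_top_features(forest, list(X.columns), k=X.shape[1])
        assert set(top["feature"]) == set(X.columns)


class TestPredictUnknowns:
    def _models(self):
        X, labels = _separable(12)
        cfg = am.ModelConfig(forest_n_trees=50, seed=5)
        model = am.train_forest(X, labels, cfg)
        return {"both": (model, list(X.columns))}, X

    def test_empty_unknown_set(self):
        models, X = self._models()
        out = am.predict_unknowns(models, {"both": X.iloc[:0]})
        assert out.empty

    def test_output_is_permutation_sorted_by_both(self):
        models, X = self._models()
        out = am.predict_unknowns(models, {"both": X})
        assert sorted(out.index) == sorted(X.index)
        probs = out["prediction_both"].to_numpy()
        assert (np.diff(probs) <= 0).all()
        assert out["rank"].tolist() == list(range(1, len(out) + 1))

    def test_planted_promoters_rank_above_inhibitors(self):
        diffs = []
        for s in range(20):
            cfg = tiny_config(seed=300 + s, n_unknown=10,
                              planted_activity_rate=0.8)
            bundle = am.simulate_bundle(cfg)
            tp = bundle.study_activity.binarize()
            labels = bundle.labels["label"]
            lab = labels[labels != am.UNKNOWN]
            unk = labels[labels == am.UNKNOWN].index
            fm = am.fuse_features(tp, None, "TP_only")
            model = am.train_forest(fm.values.loc[lab.index], lab,
                                    am.ModelConfig(forest_n_trees=100, seed=s))
            out = am.predict_unknowns({"both": (model, list(fm.values.columns))},
                                      {"both": fm.values.loc[unk]})
            truth = bundle.truth.true_labels
            pro = [c for c in unk if truth[c] == P]
            inh = [c for c in unk if truth[c] == I]
            if pro and inh:
                diffs.append(out.loc[pro, "prediction_both"].mean()
                             - out.loc[inh, "prediction_both"].mean())
        assert np.mean(diffs) > 0
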