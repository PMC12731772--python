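"""Confusion metrics, kappa, one-vs-rest AUC and ANOVA-F importances
against hand computations, brute-force oracles and sklearn cross-checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.feature_selection import f_classif
from sklearn.metrics import roc_auc_score

from t2drisk.evaluation import (
    anova_f_scores,
    confusion_and_metrics,
    format_percent,
    ovr_roc_auc,
    report_to_text,
)


def brute_force_auc(scores, labels):
    """Concordant-pair counting with ties credited 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        y = np.array(list("ABCD") * 5)
        _, report = confusion_and_metrics(y, y)
        assert report["accuracy"] == 1.0 and report["kappa"] == 1.0
        assert all(r["f1"] == 1.0 for r in report["per_class"].values())

    def test_hand_computed_binary_kappa(self):
        # confusion [[8,2],[3,7]]: p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        y_true = ["P"] * 10 + ["N"] * 10
        y_pred = ["P"] * 8 + ["N"] * 2 + ["P"] * 3 + ["N"] * 7
        cm, report = confusion_and_metrics(y_true, y_pred, classes=["P", "N"])
        assert cm.loc["P", "P"] == 8 and cm.loc["N", "P"] == 3
        assert report["accuracy"] == pytest.approx(0.75)
        assert report["kappa"] == pytest.approx(0.5)

    def test_constant_predictor_chance_level(self):
        y = np.array(list("ABCD") * 10)
        with pytest.warns(UserWarning, match="zero denominator"):
            _, report = confusion_and_metrics(y, np.array(["A"] * 40))
        assert report["accuracy"] == pytest.approx(0.25)
        assert report["kappa"] == pytest.approx(0.0)
        assert report["per_class"]["B"]["precision"] == 0.0

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(0)
        y = rng.choice(list("ABCD"), 200)
        pred = rng.choice(list("ABCD"), 200)
        _, report = confusion_and_metrics(y, pred)
        assert report["weighted"]["recall"] == pytest.approx(report["accuracy"])

    def test_trace_identity(self):
        rng = np.random.default_rng(1)
        y = rng.choice(list("AB"), 50)
        pred = rng.choice(list("AB"), 50)
        cm, report = confusion_and_metrics(y, pred)
        assert report["accuracy"] == pytest.approx(np.trace(cm) / 50)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([], [])


class TestOvrAuc:
    def test_perfect_separation(self):
        P = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        auc = ovr_roc_auc(P, np.array(["A", "A", "B", "B"]), classes=("A", "B"))
        assert auc["per_class"]["A"] == 1.0 and auc["macro"] == 1.0

    def test_hand_counted_pairs(self):
        scores = np.array([0.35, 0.8, 0.1, 0.4])
        labels = np.array(["X", "X", "Y", "Y"])
        P = np.column_stack([scores, 1 - scores])
        auc = ovr_roc_auc(P, labels, classes=("X", "Y"))
        assert auc["per_class"]["X"] == pytest.approx(0.75)

    def test_all_ties_half(self):
        P = np.full((10, 2), 0.5)
        y = np.array(["X"] * 5 + ["Y"] * 5)
        assert ovr_roc_auc(P, y, classes=("X", "Y"))["macro"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_rank_formula_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        # discrete scores force plenty of ties
        scores = rng.integers(0, 5, n) / 4
        P = np.column_stack([scores, 1 - scores])
        y = np.where(labels == 1, "P", "N")
        auc = ovr_roc_auc(P, y, classes=("P", "N"))["per_class"]["P"]
        assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(5)
        scores = rng.random(100)
        labels = (rng.random(100) < scores).astype(int)
        P = np.column_stack([scores, 1 - scores])
        y = np.where(labels == 1, "P", "N")
        ours = ovr_roc_auc(P, y, classes=("P", "N"))["per_class"]["P"]
        assert ours == pytest.approx(roc_auc_score(labels, scores))

    def test_macro_is_unweighted_mean(self, fitted_results):
        auc = fitted_results.reports[("test", "raw")]["auc"]
        assert auc["macro"] == pytest.approx(np.mean(list(auc["per_class"].values())))

    def test_single_class_dichotomy_raises(self):
        P = np.full((4, 2), 0.5)
        with pytest.raises(ValueError, match="AUC undefined"):
            ovr_roc_auc(P, np.array(["X"] * 4), classes=("X", "Y"))


class TestAnovaF:
    def test_hand_computed_two_groups(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        res = anova_f_scores(X, np.array(["a", "a", "b", "b"]))
        row = res.loc["x"]
        assert row["ss_between"] == pytest.approx(4.0)
        assert row["ss_within"] == pytest.approx(1.0)
        assert row["F"] == pytest.approx(8.0)
        assert (row["df_between"], row["df_within"]) == (1, 2)

    def test_identical_group_means_null(self):
        X = pd.DataFrame({"x": [1.0, 3.0, 1.0, 3.0]})
        res = anova_f_scores(X, np.array(["a", "a", "b", "b"]))
        assert res.loc["x", "F"] == pytest.approx(0.0)

    def test_zero_within_variance_flagged_infinite(self):
        X = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0]})
        res = anova_f_scores(X, np.array(["a", "a", "b", "b"]))
        assert np.isinf(res.loc["x", "F"]) and res.loc["x", "infinite"]

    def test_degrees_of_freedom_error(self):
        with pytest.raises(ValueError):
            anova_f_scores(pd.DataFrame({"x": [1.0, 2.0]}), np.array(["a", "b"]))

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = rng.choice(list("abc"), 60)
        f1 = anova_f_scores(pd.DataFrame({"x": x}), y).loc["x", "F"]
        f2 = anova_f_scores(pd.DataFrame({"x": 3.7 * x - 11.0}), y).loc["x", "F"]
        assert f1 == pytest.approx(f2)

    def test_matches_sklearn_f_classif(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 3))
        y = rng.choice([0, 1, 2], 80)
        ours = anova_f_scores(pd.DataFrame(X), y)["F"].to_numpy()
        ref, _ = f_classif(X, y)
        assert np.allclose(ours, ref)

    def test_cohort_feature_ranking(self, fitted_results):
        F = fitted_results.anova["F"]
        assert F["age"] > F["sex"] and F["age"] > F["smoking"]
        assert F["weight"] > F["sex"] and F["weight"] > F["smoking"]


class TestReporting:
    def test_percent_format(self):
        assert format_percent(0.915) == "91.50%"
        assert format_percent(1.0) == "100.00%"

    def test_text_report_contains_metrics(self):
        y = np.array(list("ABCD") * 5)
        _, report = confusion_and_metrics(y, y)
        text = report_to_text(report, title="demo")
        assert "accuracy : 100.00%" in text
        assert "kappa" in text and "macro" in text
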