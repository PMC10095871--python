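"""Confusion matrices, metric formulas and identities, splits, CV, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ncrclass.evaluation import (
    binary_metrics,
    confusion_matrix,
    feature_summary,
    kfold_cv,
    kfold_indices,
    per_class_metrics,
    split,
)
from ncrclass.fixtures import FixtureSpec, make_feature_clusters


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = ["a", "b", "c", "a"]
        cm = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_forced_single_cell(self):
        cm = confusion_matrix(["a"] * 5, ["b"] * 5, ["a", "b"])
        assert cm.counts[0, 1] == 5 and cm.counts.sum() == 5

    def test_hand_tally_three_classes(self):
        true = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        pred = ["a", "b", "c", "b", "b", "a", "c", "c", "b"]
        cm = confusion_matrix(true, pred, ["a", "b", "c"])
        expected = np.array([[1, 1, 1], [1, 2, 0], [0, 1, 2]])
        assert np.array_equal(cm.counts, expected)
        assert cm.total == 9

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in the class list"):
            confusion_matrix(["a"], ["z"], ["a", "b"])

    def test_one_vs_rest_collapse_sums_to_total(self):
        rng = np.random.default_rng(5)
        classes = ["a", "b", "c", "d"]
        true = rng.choice(classes, 60)
        pred = rng.choice(classes, 60)
        cm = confusion_matrix(true, pred, classes)
        for c in classes:
            tp, fn, fp, tn = cm.one_vs_rest(c)
            assert tp + fn + fp + tn == cm.total


class TestMetrics:
    def test_worked_example(self):
        """TP=90, FN=10, FP=5, TN=95 reproduces the nine standard metrics."""
        m = binary_metrics(tp=90, fn=10, fp=5, tn=95)
        assert m["sensitivity"] == pytest.approx(0.9000)
        assert m["specificity"] == pytest.approx(0.9500)
        assert m["ppv"] == pytest.approx(0.94737, abs=5e-6)
        assert m["npv"] == pytest.approx(0.90476, abs=5e-6)
        assert m["fpr"] == pytest.approx(0.05)
        assert m["fnr"] == pytest.approx(0.10)
        assert m["fdr"] == pytest.approx(1 - 0.94737, abs=5e-6)
        assert m["accuracy"] == pytest.approx(0.925)
        assert m["f1"] == pytest.approx(0.92308, abs=5e-6)

    def test_perfect_diagonal(self):
        cm = confusion_matrix(["a", "b"], ["a", "b"], ["a", "b"])
        rep = per_class_metrics(cm)
        assert (rep.per_class[["sensitivity", "specificity", "f1"]] == 1).all().all()
        assert (rep.per_class[["fpr", "fnr", "fdr"]] == 0).all().all()
        assert rep.micro_accuracy == 1.0

    def test_absent_class_flagged_undefined(self):
        cm = confusion_matrix(["a", "a"], ["a", "b"], ["a", "b"])
        rep = per_class_metrics(cm)
        assert np.isnan(rep.per_class.loc["b", "sensitivity"])
        assert rep.undefined().loc["b", "sensitivity"]

    def test_micro_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(0)
        classes = list("abc")
        true = rng.choice(classes, 50)
        pred = rng.choice(classes, 50)
        cm = confusion_matrix(true, pred, classes)
        rep = per_class_metrics(cm)
        assert rep.micro_accuracy == pytest.approx(np.trace(cm.counts) / 50)

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500),
            st.integers(0, 500), st.integers(0, 500),
        )
    )
    @settings(max_examples=300)
    def test_complementarity_identities(self, counts):
        """sens+FNR = spec+FPR = PPV+FDR = 1 whenever defined."""
        tp, fn, fp, tn = counts
        m = binary_metrics(tp, fn, fp, tn)
        if tp + fn > 0:
            assert abs(m["sensitivity"] + m["fnr"] - 1) < 1e-12
        if tn + fp > 0:
            assert abs(m["specificity"] + m["fpr"] - 1) < 1e-12
        if tp + fp > 0:
            assert abs(m["ppv"] + m["fdr"] - 1) < 1e-12
        if np.isfinite(m["f1"]):
            s, p = m["sensitivity"], m["ppv"]
            assert m["f1"] == pytest.approx(2 * p * s / (p + s))


class TestSplit:
    @pytest.fixture
    def data(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 3))
        y = np.repeat(list("abcd"), 25)
        return X, y

    @pytest.mark.parametrize("fraction,n_train", [(0.5, 50), (0.8, 80), (0.95, 95)])
    def test_protocol_fractions(self, data, fraction, n_train):
        X, y = data
        (Xtr, ytr), (Xte, yte) = split(X, y, fraction, seed=0)
        assert len(ytr) == n_train and len(yte) == 100 - n_train

    def test_partition_disjoint_exhaustive(self, data):
        X, y = data
        X = np.arange(100).reshape(-1, 1)  # identifiable rows
        (Xtr, _), (Xte, _) = split(X, y, 0.5, seed=3)
        ids = np.concatenate([Xtr[:, 0], Xte[:, 0]])
        assert sorted(ids) == list(range(100))

    def test_same_seed_identical(self, data):
        X, y = data
        a = split(X, y, 0.8, seed=9)
        b = split(X, y, 0.8, seed=9)
        assert np.array_equal(a[0][0], b[0][0]) and np.array_equal(a[1][0], b[1][0])

    def test_stratification(self, data):
        X, y = data
        (_, ytr), (_, yte) = split(X, y, 0.8, seed=0)
        for cls in "abcd":
            assert (ytr == cls).sum() == 20 and (yte == cls).sum() == 5

    def test_singleton_class_degrades_with_warning(self, caplog):
        X = np.zeros((5, 1))
        y = np.array(["a", "a", "a", "a", "b"])
        with caplog.at_level("WARNING"):
            (_, ytr), (_, yte) = split(X, y, 0.5, seed=0)
        assert "b" in "".join(caplog.messages)
        assert "b" in ytr  # kept on the training side

    def test_invalid_fraction(self, data):
        X, y = data
        with pytest.raises(ValueError):
            split(X, y, 1.0)


class TestKfold:
    def test_five_folds_partition(self):
        y = np.repeat(list("abcd"), 25)
        folds = kfold_indices(y, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(f) == 20 for f in folds)
        combined = np.concatenate(folds)
        assert sorted(combined) == list(range(100))  # disjoint + exhaustive

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_partition_for_any_seed(self, seed):
        y = np.repeat(list("ab"), 15)
        folds = kfold_indices(y, k=5, seed=seed)
        assert sorted(np.concatenate(folds)) == list(range(30))

    def test_separable_fixture_high_macro_f1(self):
        df, y = make_feature_clusters(FixtureSpec(n_per_class=30, seed=1))
        _, avg = kfold_cv(df, y, k=5, seed=0)
        assert avg.macro["f1"] >= 0.95

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(np.zeros((3, 2)), ["a", "b", "a"], k=5)


class TestFeatureSummary:
    def test_constant_feature_flagged(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        out = feature_summary(df, ["a"] * 3)
        row = out.iloc[0]
        assert row["sd"] == 0
        assert np.isnan(row["skewness"]) and np.isnan(row["kurtosis"])

    def test_symmetric_two_point_sample(self):
        df = pd.DataFrame({"x": [-1.0, 1.0]})
        out = feature_summary(df, ["a", "a"])
        row = out.iloc[0]
        assert row["mean"] == 0 and row.skewness == pytest.approx(0.0)

    def test_gaussian_moments_recovered(self):
        rng = np.random.default_rng(42)
        n, mu, sd = 10_000, 3.0, 2.0
        df = pd.DataFrame({"x": rng.normal(mu, sd, n)})
        out = feature_summary(df, ["a"] * n).iloc[0]
        assert abs(out["mean"] - mu) < 3 * sd / np.sqrt(n)
        assert abs(out["sd"] - sd) < 3 * sd / np.sqrt(2 * n)
        assert abs(out["skewness"]) < 3 * np.sqrt(6 / n)
        assert abs(out["kurtosis"]) < 3 * np.sqrt(24 / n)

    def test_per_class_rows(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4.0], "y": [0, 0, 1, 1.0]})
        out = feature_summary(df, ["a", "a", "b", "b"])
        assert set(zip(out["class"], out["feature"])) == {
            ("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")
        }
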