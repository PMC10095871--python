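"""Confusion matrices, per-class metrics, split protocols and k-fold CV.

Metrics are computed per class by one-vs-rest collapse of the multi-class
confusion matrix: sensitivity (TPR), specificity (TNR), PPV, NPV, FPR, FNR,
FDR, accuracy and F1, plus their macro (unweighted) averages. A ratio with a
zero denominator is reported as NaN together with an ``undefined`` flag —
never silently as 0, which would corrupt averages.

Splits and cross-validation folds are stratified by class (the reported
class sizes in real ncRNA corpora differ by more than an order of
magnitude; unstratified splits can starve small classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classifier import ModelSpec, train

log = logging.getLogger(__name__)

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "fpr",
    "fnr",
    "fdr",
    "accuracy",
    "f1",
)


@dataclass
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # rows = true, columns = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class against all others."""
        k = self.classes.index(cls)
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str],
) -> ConfusionMatrix:
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("true and predicted label sequences differ in length")
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(y) | set(p)) - set(index)
    if unknown:
        raise ValueError(f"labels not in the class list: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, q in zip(y, p):
        counts[index[t], index[q]] += 1
    return ConfusionMatrix(tuple(classes), counts)


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """The nine metrics from one class's one-vs-rest counts (NaN if undefined)."""

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
        else float("nan")
    )
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "fpr": 1 - spec if np.isfinite(spec) else float("nan"),
        "fnr": 1 - sens if np.isfinite(sens) else float("nan"),
        "fdr": 1 - ppv if np.isfinite(ppv) else float("nan"),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "f1": f1,
    }


@dataclass
class MetricsReport:
    per_class: pd.DataFrame  # index = classes, columns = METRIC_NAMES
    micro_accuracy: float  # trace / total

    @property
    def macro(self) -> pd.Series:
        """Unweighted mean over classes; NaN cells excluded with a warning."""
        if self.per_class.isna().any().any():
            log.warning("macro averages computed with undefined cells excluded")
        return self.per_class.mean(axis=0, skipna=True)

    def undefined(self) -> pd.DataFrame:
        return self.per_class.isna()

    def to_json_dict(self) -> dict:
        return {
            "per_class": {
                c: {m: _none_if_nan(v) for m, v in row.items()}
                for c, row in self.per_class.iterrows()
            },
            "macro": {m: _none_if_nan(v) for m, v in self.macro.items()},
            "micro_accuracy": self.micro_accuracy,
        }


def _none_if_nan(v: float) -> float | None:
    return None if not np.isfinite(v) else float(v)


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = {c: binary_metrics(*cm.one_vs_rest(c)) for c in cm.classes}
    per_class = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    micro = float(np.trace(cm.counts) / cm.total)
    return MetricsReport(per_class=per_class, micro_accuracy=micro)


def split(
    X: np.ndarray,
    labels: Sequence[str],
    train_fraction: float,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Stratified, reproducible train/test partition.

    Returns ((X_train, y_train), (X_test, y_test)); together they are a
    disjoint, exhaustive partition of the input rows. Classes with a single
    member cannot be stratified; they are placed on the training side with a
    warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(labels)
    n = len(y)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    singles: list[np.ndarray] = []
    strat: list[np.ndarray] = []
    for cls in sorted(set(y)):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            log.warning("class %r has < 2 members; kept on the training side", cls)
            singles.append(idx)
        else:
            strat.append(idx)
    # largest-remainder allocation: per-class train counts sum to the exact
    # overall train size round(fraction * n)
    n_single = sum(len(s) for s in singles)
    target_total = int(round(train_fraction * n)) - n_single
    targets = [train_fraction * len(idx) for idx in strat]
    counts = [min(max(int(t), 1), len(idx) - 1) for t, idx in zip(targets, strat)]
    remainders = sorted(
        range(len(strat)), key=lambda i: targets[i] - counts[i], reverse=True
    )
    changed = True
    while sum(counts) < target_total and changed:
        changed = False
        for i in remainders:
            if sum(counts) >= target_total:
                break
            if counts[i] < len(strat[i]) - 1:
                counts[i] += 1
                changed = True
    for idx in singles:
        train_idx.extend(idx)
    for idx, n_tr in zip(strat, counts):
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_tr])
        test_idx.extend(perm[n_tr:])
    train_idx_a = np.sort(np.asarray(train_idx, dtype=int))
    test_idx_a = np.sort(np.asarray(test_idx, dtype=int))
    return (X[train_idx_a], y[train_idx_a]), (X[test_idx_a], y[test_idx_a])


def kfold_cv(
    X: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    k: int = 5,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation of the SVM.

    The folds partition the dataset into k near-equal, non-overlapping parts;
    each part is the held-out test set exactly once while the other k-1 train
    the classifier. Returns the per-fold reports and a report whose cells are
    the arithmetic mean over folds (micro-accuracy averaged likewise).
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("k exceeds the dataset size")
    spec = spec or ModelSpec()
    classes = tuple(sorted(set(y)))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for tr, te in skf.split(X, y):
        model = train(X[tr], y[tr], spec)
        pred, _ = model.predict(X[te])
        cm = confusion_matrix(y[te], pred, classes)
        reports.append(per_class_metrics(cm))
    mean_frame = (
        pd.concat([r.per_class for r in reports]).groupby(level=0, sort=False).mean()
    ).loc[list(classes)]
    averaged = MetricsReport(
        per_class=mean_frame,
        micro_accuracy=float(np.mean([r.micro_accuracy for r in reports])),
    )
    return reports, averaged


def kfold_indices(
    labels: Sequence[str], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """The test-fold index sets of the stratified k-fold partition."""
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [te for _, te in skf.split(np.zeros((len(y), 1)), y)]


def feature_summary(
    features: pd.DataFrame, labels: Sequence[str], columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-class summary of each feature: mean, median, SD, min, max,
    skewness, excess kurtosis.

    Moment-based skewness/kurtosis; both are NaN for a constant feature
    (zero variance), which is the flagged-undefined convention used
    throughout. Rows are (class, feature) pairs, serialisable to TSV.
    """
    y = np.asarray(labels)
    cols = list(columns) if columns is not None else list(features.columns)
    rows = []
    for cls in sorted(set(y)):
        sub = features.loc[np.asarray(y == cls)]
        for col in cols:
            v = sub[col].to_numpy(dtype=float)
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            if sd > 0:
                skew = float(stats.skew(v, bias=True))
                kurt = float(stats.kurtosis(v, bias=True))  # excess
            else:
                skew = kurt = float("nan")
            rows.append(
                {
                    "class": cls,
                    "feature": col,
                    "n": len(v),
                    "mean": float(np.mean(v)),
                    "median": float(np.median(v)),
                    "sd": sd,
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                    "skewness": skew,
                    "kurtosis": kurt,
                }
            )
    return pd.DataFrame(rows)
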