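"""One-vs-one multi-class SVM with RBF kernel, plus grid search and persistence.

The decision machinery is scikit-learn's SVC restricted to its one-against-one
decision values; voting and tie-breaking are implemented here so the rule is
explicit: most pairwise votes wins, ties broken by the larger aggregate
decision-function margin, remaining ties by class-label order.

Defaults follow the tuned operating point for the 70-feature ncRNA problem:
C = 8, gamma = 0.003, z-score feature scaling on. gamma may also be given as
the rule "1/n" (one over the number of features), the conventional pre-search
default for RBF kernels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_NAMES, feature_fingerprint

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

GAMMA_RULE = "1/n"


class ModelError(ValueError):
    """Bad training input, corrupted model file, or fingerprint mismatch."""


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters and bookkeeping for one training run."""

    C: float = 8.0
    gamma: float | str = 0.003
    class_labels: tuple[str, ...] | None = None  # None: infer from data, sorted
    scaling: str = "z-score"  # "z-score" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ModelError("C must be positive")
        if isinstance(self.gamma, str):
            if self.gamma != GAMMA_RULE:
                raise ModelError(f"gamma must be positive or the rule {GAMMA_RULE!r}")
        elif self.gamma <= 0:
            raise ModelError("gamma must be positive")
        if self.scaling not in ("z-score", "none"):
            raise ModelError("scaling must be 'z-score' or 'none'")
        if self.class_labels is not None and len(set(self.class_labels)) < 2:
            raise ModelError("need at least 2 distinct class labels")

    def resolved_gamma(self, n_features: int) -> float:
        if self.gamma == GAMMA_RULE:
            return 1.0 / n_features
        return float(self.gamma)


@dataclass
class TrainedModel:
    """Fitted one-vs-one SVM plus the scaling applied at train time."""

    svc: SVC
    spec: ModelSpec
    classes: tuple[str, ...]
    center: np.ndarray  # per-feature center (zeros when scaling == none)
    spread: np.ndarray  # per-feature spread (ones when scaling == none)
    fingerprint: str
    n_train_per_class: dict[str, int] = field(default_factory=dict)

    def _check(self, X: np.ndarray, fingerprint: str | None) -> np.ndarray:
        if fingerprint is not None and fingerprint != self.fingerprint:
            raise ModelError(
                "feature-order fingerprint mismatch: the vectors were not "
                "produced with the feature order this model was trained on"
            )
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ModelError("non-finite feature values")
        return (X - self.center) / self.spread

    def predict(
        self, X: np.ndarray, fingerprint: str | None = None
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """Predicted labels plus a per-class vote/margin score table.

        Each of the K(K-1)/2 pairwise machines votes; the class with most
        votes wins. Vote ties are broken by the aggregate decision-function
        margin (sum of signed pairwise decision values), then by class order.
        """
        Xs = self._check(X, fingerprint)
        K = len(self.classes)
        decision = np.atleast_2d(self.svc.decision_function(Xs))
        if K == 2:
            # sklearn collapses ovo to one binary column where d > 0 means
            # classes_[1]; negate so the multi-class convention below applies
            decision = -decision.reshape(-1, 1)
        votes = np.zeros((Xs.shape[0], K))
        margins = np.zeros((Xs.shape[0], K))
        col = 0
        # ovo columns run (0,1),(0,2),...,(K-2,K-1); d > 0 favors the
        # first class of the pair (libsvm convention)
        for a in range(K):
            for b in range(a + 1, K):
                d = decision[:, col]
                votes[:, a] += d > 0
                votes[:, b] += d <= 0
                margins[:, a] += d
                margins[:, b] -= d
                col += 1
        # lexicographic argmax: votes, then margin, then class order
        order = np.lexsort(
            (np.arange(K)[None, :].repeat(Xs.shape[0], 0), -margins, -votes), axis=1
        )
        winner = order[:, 0]
        labels = np.array([self.classes[w] for w in winner])
        scores = pd.DataFrame(votes, columns=list(self.classes))
        for k, cls in enumerate(self.classes):
            scores[f"margin_{cls}"] = margins[:, k]
        return labels, scores


def train(
    X: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    spec: ModelSpec | None = None,
    fingerprint: str | None = None,
) -> TrainedModel:
    """Fit the one-vs-one SVM-RBF on a feature table.

    Scaling statistics are computed from the training rows only and stored in
    the model, so prediction applies exactly the train-time transformation.
    """
    spec = spec or ModelSpec()
    if isinstance(X, pd.DataFrame):
        if fingerprint is None and list(X.columns) == list(FEATURE_NAMES):
            fingerprint = feature_fingerprint()
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ModelError("rows and labels are not aligned")
    if not np.isfinite(X).all():
        raise ModelError("non-finite feature values in training data")
    present = sorted(set(y))
    if len(present) < 2:
        raise ModelError("single-class input: need at least 2 classes to train")
    if spec.class_labels is not None:
        unknown = set(present) - set(spec.class_labels)
        if unknown:
            raise ModelError(f"labels not in class_labels: {sorted(unknown)}")
        classes = tuple(spec.class_labels)
    else:
        classes = tuple(present)

    if spec.scaling == "z-score":
        center = X.mean(axis=0)
        spread = X.std(axis=0)
        spread[spread == 0] = 1.0  # constant features pass through unscaled
    else:
        center = np.zeros(X.shape[1])
        spread = np.ones(X.shape[1])
    Xs = (X - center) / spread

    svc = SVC(
        C=spec.C,
        kernel="rbf",
        gamma=spec.resolved_gamma(X.shape[1]),
        decision_function_shape="ovo",
        random_state=spec.seed,
    )
    svc.fit(Xs, y)
    # sklearn orders its ovo machines by sorted class labels; mirror that
    fitted_classes = tuple(str(c) for c in svc.classes_)
    counts = {c: int((y == c).sum()) for c in fitted_classes}
    return TrainedModel(
        svc=svc,
        spec=replace(spec, class_labels=classes),
        classes=fitted_classes,
        center=center,
        spread=spread,
        fingerprint=fingerprint or feature_fingerprint(),
        n_train_per_class=counts,
    )


def predict(
    model: TrainedModel,
    X: np.ndarray | pd.DataFrame,
    fingerprint: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply a trained model to a feature table; see TrainedModel.predict."""
    if isinstance(X, pd.DataFrame):
        if fingerprint is None and list(X.columns) == list(FEATURE_NAMES):
            fingerprint = feature_fingerprint()
        X = X.to_numpy(dtype=float)
    return model.predict(X, fingerprint=fingerprint)


def grid_search(
    X: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    C_grid: Sequence[float],
    gamma_grid: Sequence[float],
    train_fraction: float = 0.8,
    spec: ModelSpec | None = None,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Pick (C, gamma) minimising held-out error on a stratified 80/20 split.

    Every grid cell is trained on the same split and scored by error rate on
    the test side. Ties go to the smallest C, then the smallest gamma.
    Returns the winning pair and the full error table.
    """
    from .evaluation import split  # local import to avoid cycle

    if not len(C_grid) or not len(gamma_grid):
        raise ModelError("empty hyperparameter grid")
    base = spec or ModelSpec()
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    (Xtr, ytr), (Xte, yte) = split(X, y, train_fraction, seed=base.seed)
    if len(yte) == 0:
        raise ModelError("degenerate split: empty test side")
    rows = []
    best: tuple[float, float, float] | None = None  # (error, C, gamma)
    for C in C_grid:
        for gamma in gamma_grid:
            cell = replace(base, C=float(C), gamma=float(gamma))
            model = train(Xtr, ytr, cell)
            pred, _ = model.predict(Xte)
            error = float(np.mean(pred != yte))
            rows.append({"C": float(C), "gamma": float(gamma), "error": error})
            key = (error, float(C), float(gamma))
            if best is None or key < best:
                best = key
    table = pd.DataFrame(rows)
    assert best is not None
    return (best[1], best[2]), table


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model with enough metadata to refuse mismatched inputs."""
    spec = model.spec
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "metadata": json.dumps(
            {
                "spec": {
                    "C": spec.C,
                    "gamma": spec.gamma,
                    "class_labels": list(spec.class_labels or model.classes),
                    "scaling": spec.scaling,
                    "seed": spec.seed,
                },
                "classes": list(model.classes),
                "fingerprint": model.fingerprint,
                "n_train_per_class": model.n_train_per_class,
            }
        ),
        "svc": model.svc,
        "center": model.center,
        "spread": model.spread,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelError(f"corrupted or unreadable model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelError(f"not a model file: {path}")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"model format version {payload['format_version']} "
            f"(this build reads {MODEL_FORMAT_VERSION})"
        )
    try:
        meta = json.loads(payload["metadata"])
        spec = ModelSpec(
            C=meta["spec"]["C"],
            gamma=meta["spec"]["gamma"],
            class_labels=tuple(meta["spec"]["class_labels"]),
            scaling=meta["spec"]["scaling"],
            seed=meta["spec"]["seed"],
        )
        return TrainedModel(
            svc=payload["svc"],
            spec=spec,
            classes=tuple(meta["classes"]),
            center=np.asarray(payload["center"]),
            spread=np.asarray(payload["spread"]),
            fingerprint=meta["fingerprint"],
            n_train_per_class=dict(meta["n_train_per_class"]),
        )
    except (KeyError, TypeError) as exc:
        raise ModelError(f"corrupted model file {path}: missing {exc}") from exc
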