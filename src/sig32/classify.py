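"""All-pairs (one-vs-one) linear-SVM subtype classifier.

K classes give K(K-1)/2 soft-margin linear SVMs (C = 1 by default), one per
unordered class pair. Each pairwise decision value d is mapped to a win
probability p(i beats j) = sigmoid(d / s) with a scale-free slope calibrated
on training data (s = median |training decision value|), and class-membership
probabilities aggregate the pairwise wins with uniform weights:

    score_i = sum_{j != i} p(i beats j),      prob_i = score_i / sum scores.

Performance is evaluated by leave-one-out cross-validation with per-class
one-vs-rest ROC AUC on the held-out membership probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .errors import AlignmentError, InputError


@dataclass
class LinearBinarySVM:
    """One pairwise classifier: decision value w.x + b > 0 favours class_i."""

    class_i: object
    class_j: object
    w: np.ndarray
    b: float
    C: float
    slope: float  # logistic calibration: p(i beats j) = sigmoid(slope * (w.x + b))

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b

    def win_probability(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.slope * self.decision(X)))


@dataclass
class PairwiseEnsemble:
    classes: list
    models: list[LinearBinarySVM]
    feature_names: list[str] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_json(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "feature_names": self.feature_names,
            "models": [
                {
                    "class_i": str(m.class_i),
                    "class_j": str(m.class_j),
                    "w": m.w.tolist(),
                    "b": m.b,
                    "C": m.C,
                    "slope": m.slope,
                }
                for m in self.models
            ],
        }

    @classmethod
    def from_json(cls, payload: dict) -> "PairwiseEnsemble":
        models = [
            LinearBinarySVM(
                class_i=m["class_i"], class_j=m["class_j"],
                w=np.asarray(m["w"], dtype=float), b=float(m["b"]),
                C=float(m["C"]), slope=float(m["slope"]),
            )
            for m in payload["models"]
        ]
        return cls(classes=payload["classes"], models=models,
                   feature_names=payload.get("feature_names"))


@dataclass
class CVReport:
    per_class_auc: dict
    mean_auc: float
    predictions: pd.DataFrame  # per-sample held-out probabilities + labels
    skipped: list


def _fit_pair(X: np.ndarray, y_pm: np.ndarray, ci, cj, C: float) -> LinearBinarySVM:
    svc = SVC(kernel="linear", C=C, tol=1e-6, max_iter=100_000)
    svc.fit(X, y_pm)
    # sklearn sorts classes as [-1, +1] and its decision is positive for +1;
    # we code class_i as +1 so positive decisions favour class_i.
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])
    d = X @ w + b
    med = float(np.median(np.abs(d)))
    slope = 1.0 / med if med > 0 else 1.0
    return LinearBinarySVM(class_i=ci, class_j=cj, w=w, b=b, C=C, slope=slope)


def train_pairwise(
    X: np.ndarray,
    labels: np.ndarray | list,
    C: float = 1.0,
    feature_names: list[str] | None = None,
) -> PairwiseEnsemble:
    """Train one linear SVM per unordered class pair (samples x features input)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(pd.Series(labels)).tolist())
    if len(classes) < 2:
        raise InputError("need at least two classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise InputError(f"class {c!r} has fewer than 2 samples")
    models = []
    for ci, cj in combinations(classes, 2):
        mask = (labels == ci) | (labels == cj)
        y_pm = np.where(labels[mask] == ci, 1, -1)
        models.append(_fit_pair(X[mask], y_pm, ci, cj, C))
    return PairwiseEnsemble(classes=classes, models=models, feature_names=feature_names)


def aggregate(
    pairwise_probs: dict[tuple, np.ndarray] | dict[tuple, float],
    classes: list,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Combine pairwise win probabilities into class-membership probabilities.

    ``pairwise_probs[(i, j)]`` is p(i beats j) for each sample; the implied
    p(j beats i) is its complement. Weights default to uniform over pairs
    (and a uniform vector only rescales all scores equally, leaving the
    normalized probabilities unchanged).
    """
    pairs = list(combinations(classes, 2))
    if weights is None:
        weights = np.full(len(pairs), 1.0 / len(pairs))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(pairs),):
        raise InputError("need one aggregation weight per class pair")
    first = np.atleast_1d(np.asarray(pairwise_probs[pairs[0]], dtype=float))
    n = first.shape[0]
    scores = np.zeros((n, len(classes)))
    for w, (ci, cj) in zip(weights, pairs):
        p = np.atleast_1d(np.asarray(pairwise_probs[(ci, cj)], dtype=float))
        if ((p < 0) | (p > 1)).any():
            raise InputError(f"pairwise probability for pair {(ci, cj)} outside [0, 1]")
        scores[:, classes.index(ci)] += w * p
        scores[:, classes.index(cj)] += w * (1.0 - p)
    return scores / scores.sum(axis=1, keepdims=True)


def predict_subtype(
    ensemble: PairwiseEnsemble,
    X: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and membership probabilities for new samples.

    ``X`` is samples x features in the ensemble's feature order (pass a
    DataFrame with feature columns to have the order checked). Argmax ties
    break towards the lower class index (the better-prognosis group).
    """
    if isinstance(X, pd.DataFrame):
        if ensemble.feature_names is not None:
            if list(X.columns) != list(ensemble.feature_names):
                raise AlignmentError("feature columns do not match the model's gene order")
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    probs = aggregate(
        {(m.class_i, m.class_j): m.win_probability(X) for m in ensemble.models},
        ensemble.classes,
    )
    label_idx = np.argmax(probs, axis=1)  # argmax takes the first maximum: lower index wins ties
    labels = np.asarray([ensemble.classes[i] for i in label_idx])
    return labels, probs


def loocv(X: np.ndarray, labels: np.ndarray | list, C: float = 1.0) -> CVReport:
    """Leave-one-out cross-validation with per-class one-vs-rest AUC."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    classes = sorted(pd.unique(pd.Series(labels)).tolist())
    if n < len(classes) + 1:
        raise InputError("too few samples for leave-one-out")
    probs = np.full((n, len(classes)), np.nan)
    skipped = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        counts = pd.Series(labels[keep]).value_counts()
        if len(counts) < len(classes) or counts.min() < 2:
            skipped.append(i)
            warnings.warn(f"LOOCV fold {i} would lose a class; skipped")
            continue
        ens = train_pairwise(X[keep], labels[keep], C=C)
        _, p = predict_subtype(ens, X[i : i + 1])
        probs[i] = p[0]
    valid = ~np.isnan(probs[:, 0])
    per_class = {}
    for j, c in enumerate(classes):
        y = (labels[valid] == c).astype(int)
        per_class[c] = float(roc_auc_score(y, probs[valid, j])) if 0 < y.sum() < y.size else np.nan
    mean_auc = float(np.nanmean(list(per_class.values())))
    predictions = pd.DataFrame(probs, columns=[f"prob_{c}" for c in classes])
    predictions["label"] = labels
    return CVReport(per_class_auc=per_class, mean_auc=mean_auc,
                    predictions=predictions, skipped=skipped)
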