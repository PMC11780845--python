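"""Supervised nucleus/impurity classification from six-parameter features.

A desk-scale learned baseline over the same feature vectors the scoring table
uses: standardized features into either a regularized logistic regression
(default) or a small random-forest ensemble.  Six features do not justify
anything deeper.  Standardization statistics are learned on the training
split only, and trained models round-trip through plain JSON (coefficients or
tree tables — no binary blobs), with prediction implemented directly on the
stored arrays so a loaded model needs nothing but numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .morphometry import FeatureVector
from .scoring import IMPURITY, NUCLEUS
from .stains import StainMethod

TRAIN, VAL, TEST = "train", "val", "test"


@dataclass
class LabeledFeature:
    """One labeled object: features, stain, true label and split assignment."""

    features: FeatureVector
    stain: StainMethod
    label: str
    split: str | None = None

    def __post_init__(self):
        self.stain = StainMethod.parse(self.stain)
        if self.label not in (NUCLEUS, IMPURITY):
            raise ValueError(f"label must be {NUCLEUS!r} or {IMPURITY!r}")
        if self.split not in (None, TRAIN, VAL, TEST):
            raise ValueError(f"unknown split {self.split!r}")


def _design_matrix(items: list[LabeledFeature]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([it.features.as_array() for it in items], dtype=float)
    y = np.array([it.label for it in items])
    return X, y


@dataclass
class ModelConfig:
    """Classifier family and its knobs."""

    family: str = "linear"            # "linear" or "forest"
    C: float = 1.0                    # inverse L2 strength (linear)
    n_estimators: int = 50            # forest size
    max_depth: int | None = 6

    def __post_init__(self):
        if self.family not in ("linear", "forest"):
            raise ValueError("family must be 'linear' or 'forest'")


class FeatureClassifier:
    """A trained model in a self-contained, JSON-serializable form.

    Linear: class score = (x - mean) / scale @ coef + intercept.
    Forest: mean leaf class distribution over the stored trees.
    """

    def __init__(self, family: str, classes: list[str], payload: dict,
                 scaler_mean: np.ndarray, scaler_scale: np.ndarray):
        self.family = family
        self.classes = list(classes)
        self.payload = payload
        self.scaler_mean = np.asarray(scaler_mean, dtype=float)
        self.scaler_scale = np.asarray(scaler_scale, dtype=float)

    # -- prediction ---------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(np.atleast_2d(X))
        if self.family == "linear":
            logits = Z @ np.asarray(self.payload["coef"]) + self.payload["intercept"]
            p1 = 1.0 / (1.0 + np.exp(-logits))
            return np.stack([1.0 - p1, p1], axis=1)
        probs = np.zeros((len(Z), len(self.classes)))
        for tree in self.payload["trees"]:
            probs += _tree_predict(tree, Z)
        return probs / len(self.payload["trees"])

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        return np.array([self.classes[i] for i in idx])

    def predict_items(self, items: list[LabeledFeature]) -> np.ndarray:
        X, _ = _design_matrix(items)
        return self.predict(X)

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "classes": self.classes,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "payload": self.payload,
            "feature_names": list(FeatureVector.PARAMETERS),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureClassifier":
        return cls(family=data["family"], classes=data["classes"],
                   payload=data["payload"], scaler_mean=data["scaler_mean"],
                   scaler_scale=data["scaler_scale"])

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FeatureClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _tree_predict(tree: dict, Z: np.ndarray) -> np.ndarray:
    left = np.asarray(tree["children_left"])
    right = np.asarray(tree["children_right"])
    feat = np.asarray(tree["feature"])
    thresh = np.asarray(tree["threshold"])
    value = np.asarray(tree["value"], dtype=float)
    out = np.zeros((len(Z), value.shape[-1]))
    for i, row in enumerate(Z):
        node = 0
        while left[node] != -1:
            node = left[node] if row[feat[node]] <= thresh[node] else right[node]
        dist = value[node].ravel()
        out[i] = dist / dist.sum()
    return out


def train_classifier(train_items: list[LabeledFeature],
                     config: ModelConfig | None = None,
                     rng: int | np.random.Generator | None = 0) -> FeatureClassifier:
    """Fit the classifier on the training split; deterministic given the seed.

    Raises ``ValueError`` if the training data holds a single class.
    """
    config = config or ModelConfig()
    X, y = _design_matrix(train_items)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")

    seed = int(np.random.default_rng(rng).integers(2**31 - 1))
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    if config.family == "linear":
        model = LogisticRegression(C=config.C, random_state=seed, max_iter=2000)
        model.fit(Z, y)
        payload = {"coef": model.coef_.ravel().tolist(),
                   "intercept": float(model.intercept_[0])}
        classes = model.classes_.tolist()
    else:
        model = RandomForestClassifier(n_estimators=config.n_estimators,
                                       max_depth=config.max_depth,
                                       random_state=seed)
        model.fit(Z, y)
        classes = model.classes_.tolist()
        payload = {"trees": [{
            "children_left": est.tree_.children_left.tolist(),
            "children_right": est.tree_.children_right.tolist(),
            "feature": est.tree_.feature.tolist(),
            "threshold": est.tree_.threshold.tolist(),
            "value": est.tree_.value.tolist(),
        } for est in model.estimators_]}
    return FeatureClassifier(family=config.family, classes=classes,
                             payload=payload, scaler_mean=mean, scaler_scale=scale)


@dataclass(frozen=True)
class EvalMetrics:
    """Per-class recall, overall accuracy and the confusion counts."""

    recall: dict[str, float]
    accuracy: float
    confusion: dict[str, dict[str, int]]   # confusion[true][pred]
    n: int


def evaluate_classifier(model: FeatureClassifier,
                        items: list[LabeledFeature],
                        split: str | None = None) -> EvalMetrics:
    """Confusion matrix, per-class recall (TP / (TP + FN)) and accuracy.

    If ``split`` is given, only items tagged with that split are evaluated —
    the assertion that test metrics never touch train/val items.
    """
    if split is not None:
        items = [it for it in items if it.split == split]
    if not items:
        raise ValueError("no items to evaluate")
    X, y_true = _design_matrix(items)
    y_pred = model.predict(X)
    labels = sorted(set(y_true) | set(y_pred))
    confusion = {t: {p: 0 for p in labels} for t in labels}
    for t, p in zip(y_true, y_pred):
        confusion[t][p] += 1
    recall = {}
    for t in sorted(set(y_true)):
        support = sum(confusion[t].values())
        recall[t] = confusion[t].get(t, 0) / support
    accuracy = float((y_true == y_pred).mean())
    return EvalMetrics(recall=recall, accuracy=accuracy, confusion=confusion, n=len(items))
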