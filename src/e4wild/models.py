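"""Classifier families behind one training interface.

Four model kinds — logistic regression (``lr``), random forest (``rf``),
feedforward neural network (``nn``) and mixed-effect random forest
(``merf``) — share ``fit(TrainingSet)`` / ``predict_score`` /
``predict_label``.  Event windows are the positive class; training sets are
balanced by random duplication of positive rows before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .merf import MerfClassifier

MODEL_KINDS = ("lr", "rf", "nn", "merf")

#: Small default hyper-grids; config, not doctrine.
DEFAULT_GRID: Dict[str, List[dict]] = {
    "lr": [{"C": 0.1}, {"C": 1.0}],
    "rf": [{"n_estimators": 100, "max_depth": None},
           {"n_estimators": 100, "max_depth": 6}],
    "nn": [{"hidden": 16}, {"hidden": 64}],
    "merf": [{"n_estimators": 100, "max_iter": 3}],
}


@dataclass
class TrainingSet:
    """Standardized features, binary labels and the participant cluster key."""

    X: np.ndarray
    y: np.ndarray
    clusters: np.ndarray
    feature_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.clusters = np.asarray(self.clusters)
        if self.X.shape[0] != self.y.size or self.y.size != self.clusters.size:
            raise ValueError("X, y and clusters must agree in length")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(self.y.size - self.y.sum())


def oversample_positives(train: TrainingSet, seed: int = 0) -> TrainingSet:
    """Duplicate positive rows (with replacement) until classes balance.

    Negative rows are untouched; a single-class input is an error.  With
    positives already >= negatives the set is returned unchanged.
    """
    if train.n_positive == 0 or train.n_negative == 0:
        raise ValueError("oversampling needs both classes present")
    deficit = train.n_negative - train.n_positive
    if deficit <= 0:
        return train
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(train.y == 1)
    extra = rng.choice(pos_idx, size=deficit, replace=True)
    order = np.concatenate([np.arange(train.y.size), extra])
    return TrainingSet(train.X[order], train.y[order], train.clusters[order],
                       train.feature_names)


class _SklearnModel:
    """Adapter giving sklearn classifiers the common surface."""

    def __init__(self, estimator):
        self.estimator = estimator
        self.n_features_: Optional[int] = None

    def fit(self, train: TrainingSet) -> "_SklearnModel":
        if not np.all(np.isfinite(train.X)):
            raise ValueError("non-finite features")
        self.estimator.fit(train.X, train.y)
        self.n_features_ = train.X.shape[1]
        return self

    def predict_score(self, X: np.ndarray,
                      clusters: Optional[np.ndarray] = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.n_features_ is not None and X.shape[1] != self.n_features_:
            raise ValueError("feature count mismatch with training data")
        return self.estimator.predict_proba(X)[:, 1]

    def predict_label(self, X: np.ndarray, clusters: Optional[np.ndarray] = None,
                      threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(X, clusters) >= threshold).astype(int)


class _MerfModel:
    def __init__(self, **kw):
        self.model = MerfClassifier(**kw)
        self.n_features_: Optional[int] = None

    def fit(self, train: TrainingSet) -> "_MerfModel":
        self.model.fit(train.X, train.y, train.clusters)
        self.n_features_ = train.X.shape[1]
        return self

    @property
    def state_(self):
        return self.model.state_

    def predict_score(self, X, clusters=None):
        X = np.asarray(X, dtype=float)
        if self.n_features_ is not None and X.shape[1] != self.n_features_:
            raise ValueError("feature count mismatch with training data")
        return self.model.predict_score(X, clusters)

    def predict_label(self, X, clusters=None, threshold: float = 0.5):
        return (self.predict_score(X, clusters) >= threshold).astype(int)


def make_model(kind: str, hyper: Optional[dict] = None, seed: int = 0):
    """Instantiate an unfitted model of the given kind."""
    hyper = dict(hyper or {})
    if kind == "lr":
        return _SklearnModel(LogisticRegression(
            C=hyper.get("C", 1.0), max_iter=2000, random_state=seed))
    if kind == "rf":
        return _SklearnModel(RandomForestClassifier(
            n_estimators=hyper.get("n_estimators", 100),
            max_depth=hyper.get("max_depth"), random_state=seed, n_jobs=1))
    if kind == "nn":
        return _SklearnModel(MLPClassifier(
            hidden_layer_sizes=(hyper.get("hidden", 16),),
            early_stopping=True, validation_fraction=0.15,
            max_iter=hyper.get("max_iter", 300), random_state=seed))
    if kind == "merf":
        return _MerfModel(
            n_estimators=hyper.get("n_estimators", 100),
            max_depth=hyper.get("max_depth"),
            max_iter=hyper.get("max_iter", 3),
            tol=hyper.get("tol", 1e-4),
            fix_sigma_b_zero=hyper.get("fix_sigma_b_zero", False),
            random_state=seed)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def fit_model(kind: str, train: TrainingSet, hyper: Optional[dict] = None,
              seed: int = 0):
    """Fit one model; returns an object with predict_score / predict_label."""
    return make_model(kind, hyper, seed).fit(train)
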