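"""Per-observation signed feature attributions for tree ensembles.

The primary backend walks each decision path and credits every split's
change in the node prediction to the split feature (Saabas-style tree-path
attribution), yielding one signed value per observation and feature whose
sign convention is "positive pushes toward the event class".  A permutation
importance backend (global, unsigned) is available as a fallback for
non-tree models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance


@dataclass
class ImportanceReport:
    attributions: np.ndarray      # n_obs x n_features, signed
    feature_names: List[str]
    baseline: float               # ensemble root prediction

    def ranking(self) -> pd.DataFrame:
        """All features ranked by mean |attribution|, descending."""
        mag = np.abs(self.attributions).mean(axis=0)
        df = pd.DataFrame({"feature": self.feature_names,
                           "mean_abs_attribution": mag,
                           "mean_attribution": self.attributions.mean(axis=0)})
        return df.sort_values("mean_abs_attribution",
                              ascending=False).reset_index(drop=True)

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.ranking().head(k)


def _unwrap_forest(model):
    """Accept raw sklearn forests, the package's model adapters, and MERF."""
    if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        return model
    est = getattr(model, "estimator", None)
    if isinstance(est, (RandomForestClassifier, RandomForestRegressor)):
        return est
    state = getattr(model, "state_", None)
    if state is not None and isinstance(state.forest, RandomForestRegressor):
        return state.forest
    raise TypeError(
        "tree-path attribution needs a tree ensemble; use "
        "permutation_importance_report for other model kinds")


def _tree_values(tree, is_classifier: bool) -> np.ndarray:
    v = tree.tree_.value
    if is_classifier:
        # probability of the positive class at each node
        counts = v[:, 0, :]
        return counts[:, 1] / counts.sum(axis=1)
    return v.reshape(-1)


def tree_path_attribution(model, X: np.ndarray,
                          feature_names: Optional[Sequence[str]] = None,
                          ) -> ImportanceReport:
    """Signed per-observation attributions for a fitted tree ensemble."""
    forest = _unwrap_forest(model)
    is_clf = isinstance(forest, RandomForestClassifier)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    total = np.zeros((n, p))
    baseline = 0.0
    for est in forest.estimators_:
        t = est.tree_
        values = _tree_values(est, is_clf)
        baseline += values[0]
        feature = t.feature
        # parent lookup
        parent = np.full(t.node_count, -1)
        for node in range(t.node_count):
            for child in (t.children_left[node], t.children_right[node]):
                if child != -1:
                    parent[child] = node
        paths = est.decision_path(X).tocsc()
        for node in range(t.node_count):
            par = parent[node]
            if par == -1:
                continue
            rows = paths.indices[paths.indptr[node]:paths.indptr[node + 1]]
            if rows.size:
                total[rows, feature[par]] += values[node] - values[par]
    k = len(forest.estimators_)
    return ImportanceReport(attributions=total / k,
                            feature_names=list(feature_names),
                            baseline=baseline / k)


def permutation_importance_report(model, X: np.ndarray, y: np.ndarray,
                                  feature_names: Optional[Sequence[str]] = None,
                                  n_repeats: int = 5, seed: int = 0,
                                  ) -> pd.DataFrame:
    """Global permutation importance (fallback backend, unsigned)."""
    est = getattr(model, "estimator", model)
    r = permutation_importance(est, np.asarray(X, dtype=float), np.asarray(y),
                               n_repeats=n_repeats, random_state=seed)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame({"feature": feature_names,
                       "importance": r.importances_mean,
                       "importance_sd": r.importances_std})
    return df.sort_values("importance", ascending=False).reset_index(drop=True)
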