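"""Nested cross-validation, metrics, and scenario comparisons.

The inner layer selects the (model kind, hyperparameters) pair with the best
validation accuracy; the outer layer reports accuracy, F1, precision, recall
and ROC-AUC on held-out data, with fold (or repetition) dispersion and the
majority-guess baseline.  Standardization is fit on training rows only and
positives are oversampled after standardization, inside every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES, standardize
from .models import DEFAULT_GRID, TrainingSet, fit_model, oversample_positives

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "f1", "precision", "recall", "roc_auc")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                   scores: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Accuracy/F1/precision/recall (zero conventions) and trapezoid AUC."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / max(len(y_true), 1)
    if tp + fp == 0:
        logger.debug("no positive predictions; precision set to 0")
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    out = {"accuracy": acc, "f1": f1, "precision": prec, "recall": rec}
    if scores is not None and len(set(y_true)) == 2:
        fpr, tpr, _ = roc_curve(y_true, scores)
        out["roc_auc"] = float(np.trapezoid(tpr, fpr))
    else:
        out["roc_auc"] = np.nan
    return out


def roc_threshold_sweep(scores: np.ndarray, labels: np.ndarray,
                        recall_targets: Sequence[float] = (0.7, 0.9)) -> dict:
    """Full ROC curve, trapezoid AUC and FPR at given recall levels."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    ops = {}
    for target in recall_targets:
        feasible = np.flatnonzero(tpr >= target)
        ops[target] = {"fpr": float(fpr[feasible[0]]),
                       "recall": float(tpr[feasible[0]]),
                       "threshold": float(thr[feasible[0]])}
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr, "auc": auc,
            "operating_points": ops}


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class NestedCVResult:
    scenario: str
    per_fold: pd.DataFrame            # one row per (fold, repetition)
    summary: pd.DataFrame             # metric -> mean, se
    baseline_accuracy: float
    selected: List[Tuple[str, str, dict]] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[metric, "mean"])

    def se(self, metric: str) -> float:
        return float(self.summary.loc[metric, "se"])


def _xy(table: pd.DataFrame, idx: np.ndarray, rec=None):
    sub = table.loc[idx]
    X = sub[FEATURE_NAMES].to_numpy(dtype=float)
    y = (sub["label"] == "event").astype(int).to_numpy()
    g = sub["participant"].to_numpy()
    return X, y, g


def _fit_candidate(kind: str, hyper: dict, table: pd.DataFrame,
                   train_idx: np.ndarray, seed: int):
    """Standardize on the training rows, oversample, fit."""
    std, rec = standardize(table, fit_rows=train_idx)
    X, y, g = _xy(std, train_idx)
    train = oversample_positives(TrainingSet(X, y, g, FEATURE_NAMES), seed=seed)
    model = fit_model(kind, train, hyper, seed=seed)
    return model, std


def _evaluate(model, std_table: pd.DataFrame, idx: np.ndarray) -> Dict[str, float]:
    X, y, g = _xy(std_table, idx)
    scores = model.predict_score(X, g)
    return binary_metrics(y, (scores >= 0.5).astype(int), scores)


def _candidates(grid: Dict[str, List[dict]]):
    return [(kind, hyper) for kind, hypers in grid.items() for hyper in hypers]


def run_nested_cv(table: pd.DataFrame, plan, grid: Optional[Dict] = None,
                  seed: int = 0, inner_k: int = 10,
                  max_inner_rotations: int = 4) -> NestedCVResult:
    """Run one scenario's nested CV over a feature table.

    ``plan`` is a :class:`~e4wild.splits.SplitPlan`.  Inner selection:
    explicit validation arm when the plan provides one; stratified inner
    k-fold over the training pool for the random scenario; rotated held-out
    participants for the participant scenario.  The participant scenario's
    summary weights each test participant by its share of test windows;
    other scenarios use unweighted means with standard errors.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    table = table.reset_index(drop=True)
    cands = _candidates(grid)
    rows = []
    selected = []
    rng = np.random.default_rng(seed)

    for fold in plan.folds:
        for rep in range(plan.n_repetitions):
            rep_seed = int(rng.integers(2 ** 31 - 1))
            try:
                kind, hyper = _select_candidate(
                    table, fold, cands, plan.scenario, rep_seed, inner_k,
                    max_inner_rotations)
            except _NoValidFold:
                logger.info("fold %s: no valid inner fold; skipped", fold.name)
                continue
            model, std = _fit_candidate(kind, hyper, table, fold.train, rep_seed)
            m = _evaluate(model, std, fold.test)
            y_te = (table.loc[fold.test, "label"] == "event").astype(int)
            m.update({"fold": fold.name, "rep": rep, "model": kind,
                      "participant": fold.test_participant,
                      "n_test": len(fold.test),
                      "baseline": max(1 - y_te.mean(), y_te.mean())})
            rows.append(m)
            selected.append((fold.name, kind, hyper))

    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise RuntimeError("nested CV produced no evaluable folds")
    if plan.scenario == "participant":
        w = per_fold["n_test"] / per_fold["n_test"].sum()
        means = {m: float((per_fold[m] * w).sum()) for m in METRICS}
        baseline = float((per_fold["baseline"] * w).sum())
    else:
        means = {m: float(per_fold[m].mean()) for m in METRICS}
        baseline = float(per_fold["baseline"].mean())
    ses = {m: float(per_fold[m].std(ddof=1) / np.sqrt(len(per_fold)))
           if len(per_fold) > 1 else 0.0 for m in METRICS}
    summary = pd.DataFrame({"mean": means, "se": ses})
    return NestedCVResult(scenario=plan.scenario, per_fold=per_fold,
                          summary=summary, baseline_accuracy=baseline,
                          selected=selected)


class _NoValidFold(Exception):
    pass


def _select_candidate(table, fold, cands, scenario, seed, inner_k,
                      max_inner_rotations):
    """Inner-layer model/hyperparameter selection by validation accuracy."""
    if len(cands) == 1:
        return cands[0]
    if fold.validation is not None and len(fold.validation) > 0:
        accs = []
        for kind, hyper in cands:
            model, std = _fit_candidate(kind, hyper, table, fold.train, seed)
            accs.append(_evaluate(model, std, fold.validation)["accuracy"])
        best = int(np.argmax(accs))
        return cands[best]

    if scenario == "participant":
        pool = table.loc[fold.train]
        pids = sorted(pool["participant"].unique())
        rot = pids[:max_inner_rotations]
        accs = np.zeros(len(cands))
        n_ok = 0
        for p in rot:
            va = fold.train[(pool["participant"] == p).to_numpy()]
            tr = fold.train[(pool["participant"] != p).to_numpy()]
            y_tr = (table.loc[tr, "label"] == "event").astype(int)
            if y_tr.nunique() < 2 or len(va) == 0:
                continue
            n_ok += 1
            for c, (kind, hyper) in enumerate(cands):
                model, std = _fit_candidate(kind, hyper, table, tr, seed)
                accs[c] += _evaluate(model, std, va)["accuracy"]
        if n_ok == 0:
            raise _NoValidFold
        return cands[int(np.argmax(accs))]

    # random scenario: stratified inner k-fold over the training pool
    y_pool = (table.loc[fold.train, "label"] == "event").astype(int).to_numpy()
    k = min(inner_k, int(np.bincount(y_pool).min()))
    if k < 2:
        raise _NoValidFold
    if k < inner_k:
        logger.info("inner layer: shrinking to k=%d folds", k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = np.zeros(len(cands))
    for tr_i, va_i in skf.split(np.zeros_like(y_pool), y_pool):
        tr, va = fold.train[tr_i], fold.train[va_i]
        for c, (kind, hyper) in enumerate(cands):
            model, std = _fit_candidate(kind, hyper, table, tr, seed)
            accs[c] += _evaluate(model, std, va)["accuracy"]
    return cands[int(np.argmax(accs))]


def run_temporal_per_participant(table: pd.DataFrame, grid: Optional[Dict] = None,
                                 seed: int = 0, n_repetitions: int = 10,
                                 inner_k: int = 10) -> pd.DataFrame:
    """Temporal-scenario metrics broken down per test participant.

    One model per repetition is selected/fit on the shared temporal split and
    then scored separately on each participant's slice of the hold-out set,
    giving the per-participant repetition table the personal-vs-temporal
    comparison needs.
    """
    from .splits import make_split_plan

    grid = grid if grid is not None else DEFAULT_GRID
    table = table.reset_index(drop=True)
    plan = make_split_plan(table, "temporal", seed, n_repetitions=n_repetitions)
    fold = plan.folds[0]
    cands = _candidates(grid)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repetitions):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        kind, hyper = _select_candidate(table, fold, cands, "temporal",
                                        rep_seed, inner_k, 4)
        model, std = _fit_candidate(kind, hyper, table, fold.train, rep_seed)
        te_part = table.loc[fold.test, "participant"]
        for p in sorted(te_part.unique()):
            te_p = fold.test[(te_part == p).to_numpy()]
            m = _evaluate(model, std, te_p)
            m.update({"participant": p, "rep": rep, "model": kind,
                      "n_test": len(te_p)})
            rows.append(m)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Personal vs temporal comparison, down-sampling
# ---------------------------------------------------------------------------

def compare_personal_vs_temporal(personal: pd.DataFrame, temporal: pd.DataFrame,
                                 metrics: Sequence[str] = METRICS) -> pd.DataFrame:
    """Per-participant mean increase (temporal - personal) with paired t-tests.

    Inputs are per-repetition metric tables with ``participant`` and ``rep``
    columns (e.g. built from personalized/temporal ``per_fold`` frames).
    Repetition counts must match within each participant.
    """
    rows = []
    for p in sorted(set(personal["participant"]) & set(temporal["participant"])):
        a = personal[personal["participant"] == p].sort_values("rep")
        b = temporal[temporal["participant"] == p].sort_values("rep")
        if len(a) != len(b):
            raise ValueError(f"participant {p}: unequal repetition counts "
                             f"({len(a)} vs {len(b)})")
        for m in metrics:
            diff = b[m].to_numpy() - a[m].to_numpy()
            if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
                pval = 1.0 if np.allclose(diff, 0) else np.nan
            else:
                pval = float(stats.ttest_rel(b[m], a[m]).pvalue)
            rows.append({"participant": p, "metric": m,
                         "mean_personal": float(a[m].mean()),
                         "mean_temporal": float(b[m].mean()),
                         "mean_increase": float(diff.mean()),
                         "p_value": pval, "n_reps": len(diff)})
    return pd.DataFrame(rows)


def downsample_other_participants(table: pd.DataFrame, target_participant: str,
                                  seed: int = 0) -> pd.DataFrame:
    """Subsample other participants so their total matches the target's rows.

    The quota is apportioned across the other participants by size and,
    within each, stratified by label (proportions preserved to within one
    row).  If the others jointly hold fewer rows than the target, all are
    kept (logged).
    """
    rng = np.random.default_rng(seed)
    target = table[table["participant"] == target_participant]
    others = table[table["participant"] != target_participant]
    if others.empty:
        raise ValueError("need >= 2 participants")
    n_target = len(target)
    if len(others) <= n_target:
        logger.info("other participants jointly smaller than target; keeping all")
        return table.copy()
    kept = [target]
    sizes = others.groupby("participant").size()
    raw = sizes / sizes.sum() * n_target
    quota = np.floor(raw).astype(int)
    rem = n_target - quota.sum()
    for p in raw.sub(quota).sort_values(ascending=False).index[:rem]:
        quota[p] += 1
    for p, q in quota.items():
        sub = others[others["participant"] == p]
        take = []
        by_label = sub.groupby("label").size()
        lraw = by_label / len(sub) * q
        lq = np.floor(lraw).astype(int)
        lrem = q - lq.sum()
        for lbl in lraw.sub(lq).sort_values(ascending=False).index[:lrem]:
            lq[lbl] += 1
        for lbl, nl in lq.items():
            pool = sub[sub["label"] == lbl]
            pick = rng.choice(pool.index.to_numpy(), size=min(nl, len(pool)),
                              replace=False)
            take.append(sub.loc[pick])
        kept.append(pd.concat(take))
    return pd.concat(kept).sort_index()
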