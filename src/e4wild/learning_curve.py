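"""Inverse-power-law learning curves and the training-size power analysis.

Performance as a function of training-set size is modeled as
``perf(n) = a - b * n**(-c)`` with asymptote ``a``, scale ``b`` and decay
rate ``c >= 0``.  Fits use nonlinear least squares with multiple starts.
The power analysis runs a personalized model on stratified down-samples of
one participant's training split (the test split held fixed) and fits the
law per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .evaluation import METRICS, _evaluate, _fit_candidate
from .splits import make_split_plan

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.10, 0.25, 0.50, 0.75, 0.90, 1.00)


def _ipl(n: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a - b * np.power(n, -c)


@dataclass
class LearningCurveFit:
    metric: str
    points: pd.DataFrame            # n_train, performance, repetition
    a: float
    b: float
    c: float
    residual_norm: float
    degenerate: bool = False        # flat curve: b ~ 0 or c ~ 0

    def predict(self, n: np.ndarray) -> np.ndarray:
        return _ipl(np.asarray(n, dtype=float), self.a, self.b, self.c)

    def n_for_target(self, target: float) -> Tuple[float, bool]:
        """Training size extrapolated for a target; flagged when the
        asymptote ``a`` cannot reach it."""
        if self.a <= target or self.b <= 0 or self.c <= 0:
            return np.inf, True
        n = (self.b / (self.a - target)) ** (1.0 / self.c)
        return float(n), False


def fit_inverse_power_law(n: Sequence[float], perf: Sequence[float],
                          metric: str = "", bounded: bool = True,
                          ) -> LearningCurveFit:
    """Least-squares fit of ``a - b n^-c`` with multi-start initialization."""
    n = np.asarray(n, dtype=float)
    perf = np.asarray(perf, dtype=float)
    if n.size < 3:
        raise ValueError("need >= 3 points to fit the learning curve")
    lo_a, hi_a = (0.0, 1.0) if bounded else (-np.inf, np.inf)
    bounds = ([lo_a, -np.inf, 0.0], [hi_a, np.inf, 10.0])
    best = None
    for c0 in (0.1, 0.5, 1.0, 2.0):
        for b0 in (0.5, -0.5):
            a0 = min(float(perf.max()) + 0.01, hi_a)
            try:
                popt, _ = curve_fit(_ipl, n, perf, p0=(a0, b0, c0),
                                    bounds=bounds, maxfev=20000)
            except RuntimeError:
                continue
            resid = float(np.linalg.norm(_ipl(n, *popt) - perf))
            if best is None or resid < best[1]:
                best = (popt, resid)
    if best is None:
        logger.info("learning-curve fit diverged for metric %s", metric)
        pts = pd.DataFrame({"n_train": n, "performance": perf})
        return LearningCurveFit(metric, pts, np.nan, np.nan, np.nan,
                                np.inf, degenerate=True)
    (a, b, c), resid = best
    degenerate = abs(b) < 1e-6 or c < 1e-6
    pts = pd.DataFrame({"n_train": n, "performance": perf})
    return LearningCurveFit(metric, pts, float(a), float(b), float(c),
                            resid, degenerate=degenerate)


def power_analysis(table: pd.DataFrame, participant: str,
                   model_kind: str = "rf", hyper: Optional[dict] = None,
                   fractions: Sequence[float] = DEFAULT_FRACTIONS,
                   n_repetitions: int = 10, seed: int = 0,
                   min_days: int = 8) -> Dict[str, LearningCurveFit]:
    """Learning curves for one participant's personalized model.

    The participant's temporal split fixes the test set; the training split
    is down-sampled to each fraction by stratified (label-preserving) random
    sampling — the 100% fraction runs once, the others ``n_repetitions``
    times — and an inverse power law is fit per metric.
    """
    sub = table[table["participant"] == participant].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"unknown participant {participant!r}")
    plan = make_split_plan(sub, "personalized", seed, n_repetitions=1,
                           min_days_personal=min_days)
    fold = plan.folds[0]
    rng = np.random.default_rng(seed)
    y = (sub["label"] == "event").astype(int).to_numpy()
    rows: List[Dict] = []
    for frac in fractions:
        reps = 1 if frac >= 1.0 else n_repetitions
        for rep in range(reps):
            rep_seed = int(rng.integers(2 ** 31 - 1))
            tr = _stratified_fraction(fold.train, y, frac, rep_seed)
            y_tr = y[tr]
            if y_tr.min() == y_tr.max():
                logger.info("fraction %.2f rep %d: single-class sample; skipped",
                            frac, rep)
                continue
            model, std = _fit_candidate(model_kind, hyper or {}, sub, tr, rep_seed)
            m = _evaluate(model, std, fold.test)
            m.update({"fraction": frac, "rep": rep, "n_train": len(tr)})
            rows.append(m)
    pts = pd.DataFrame(rows)
    fits: Dict[str, LearningCurveFit] = {}
    for metric in METRICS:
        ok = pts[np.isfinite(pts[metric])]
        fits[metric] = fit_inverse_power_law(ok["n_train"], ok[metric],
                                             metric=metric)
        fits[metric].points = ok[["n_train", metric, "rep", "fraction"]].rename(
            columns={metric: "performance"})
    return fits


def _stratified_fraction(idx: np.ndarray, y: np.ndarray, frac: float,
                         seed: int) -> np.ndarray:
    if frac >= 1.0:
        return idx
    rng = np.random.default_rng(seed)
    take = []
    for lbl in (0, 1):
        pool = idx[y[idx] == lbl]
        k = max(int(round(frac * pool.size)), 1) if pool.size else 0
        if k:
            take.append(rng.choice(pool, size=min(k, pool.size), replace=False))
    return np.sort(np.concatenate(take))
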