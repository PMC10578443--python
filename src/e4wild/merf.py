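"""Mixed-effect random forest (MERF) with per-cluster random intercepts.

The model is ``y_ij = f(x_ij) + b_i + eps_ij`` with a random forest for the
fixed-effect function ``f``, cluster intercepts ``b_i ~ N(0, sigma_b^2)`` and
residuals ``eps ~ N(0, sigma^2)``.  Fitting alternates an EM-style scheme:

* E-step: with ``V_i = sigma^2 I + sigma_b^2 J`` (``J`` the all-ones matrix),
  the intercept posterior mean is
  ``b_i = sigma_b^2 * sum(r_i) / (sigma^2 + n_i * sigma_b^2)`` where
  ``r_i = y_i - f(X_i)``.
* M-step: the forest is refit on ``y - b`` and the variance components are
  updated from the residuals and the intercept dispersion.

A generalized log-likelihood (GLL) trace
``sum_i [ r_i' V_i^{-1} r_i + log|V_i| ]`` is recorded per iteration and used
for the convergence check; non-monotone steps are logged, the best state is
kept.  Classification is handled via regression on 0/1 labels with scores
clipped to [0, 1].  Prediction for a cluster never seen in training uses the
forest alone, i.e. the model degrades gracefully to a plain random forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)


@dataclass
class MerfState:
    forest: RandomForestRegressor
    intercepts: Dict[object, float]
    sigma2: float
    sigma2_b: float
    gll_trace: List[float] = field(default_factory=list)
    converged: bool = False


class MerfClassifier:
    """Binary classifier: random-forest fixed effects + cluster intercepts.

    Parameters mirror :class:`~sklearn.ensemble.RandomForestRegressor` where
    they share a name.  ``fix_sigma_b_zero=True`` pins the random-intercept
    variance at zero, which makes the fit identical to a plain forest on the
    raw labels.
    """

    def __init__(self, n_estimators: int = 100, max_depth: Optional[int] = None,
                 max_iter: int = 5, tol: float = 1e-4,
                 fix_sigma_b_zero: bool = False, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_iter = max_iter
        self.tol = tol
        self.fix_sigma_b_zero = fix_sigma_b_zero
        self.random_state = random_state
        self.state_: Optional[MerfState] = None

    # -- internal -----------------------------------------------------------
    def _new_forest(self) -> RandomForestRegressor:
        # same seed every refit: with sigma_b = 0 the EM loop is then
        # exactly a plain forest fit on y
        return RandomForestRegressor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            random_state=self.random_state, n_jobs=1)

    def fit(self, X: np.ndarray, y: np.ndarray, clusters: np.ndarray,
            ) -> "MerfClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        clusters = np.asarray(clusters)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        ids, inv = np.unique(clusters, return_inverse=True)
        q = ids.size
        if q < 2 and not self.fix_sigma_b_zero:
            raise ValueError("MERF needs >= 2 clusters in training")
        n = y.size
        groups = [np.flatnonzero(inv == i) for i in range(q)]
        n_i = np.array([g.size for g in groups], dtype=float)

        b = np.zeros(q)
        sigma2, sigma2_b = 1.0, 0.0 if self.fix_sigma_b_zero else 1.0
        trace: List[float] = []
        best = None
        converged = False
        for it in range(self.max_iter):
            forest = self._new_forest()
            forest.fit(X, y - b[inv])
            fX = forest.predict(X)
            r = y - fX
            sum_r = np.array([r[g].sum() for g in groups])
            denom = sigma2 + n_i * sigma2_b
            if not self.fix_sigma_b_zero:
                b = sigma2_b * sum_r / denom
            eps = r - b[inv]
            sse = np.array([np.dot(eps[g], eps[g]) for g in groups])
            # variance-component updates (EM with the current posterior)
            tr_vinv = n_i / sigma2 - n_i * sigma2_b / (sigma2 * denom)
            sigma2_new = float(np.sum(sse + sigma2 * (n_i - sigma2 * tr_vinv)) / n)
            if self.fix_sigma_b_zero:
                sigma2_b_new = 0.0
            else:
                ones_vinv_ones = n_i / denom
                sigma2_b_new = float(np.mean(
                    b ** 2 + (sigma2_b - sigma2_b ** 2 * ones_vinv_ones)))
            # GLL at the updated state
            rr = np.array([np.dot(r[g], r[g]) for g in groups])
            quad = rr / sigma2_new - (sigma2_b_new * sum_r ** 2
                                      / (sigma2_new * (sigma2_new + n_i * sigma2_b_new)))
            logdet = (n_i - 1) * np.log(sigma2_new) \
                + np.log(sigma2_new + n_i * sigma2_b_new)
            gll = float(np.sum(quad + logdet))
            if trace and gll > trace[-1] + 1e-9:
                logger.info("MERF GLL increased at iteration %d (%.4f -> %.4f)",
                            it, trace[-1], gll)
            trace.append(gll)
            sigma2 = max(sigma2_new, 1e-8)
            sigma2_b = max(sigma2_b_new, 0.0)
            state = MerfState(forest=forest,
                              intercepts=dict(zip(ids.tolist(), b.tolist())),
                              sigma2=sigma2, sigma2_b=sigma2_b,
                              gll_trace=list(trace))
            if best is None or gll <= min(trace[:-1], default=np.inf):
                best = state
            if len(trace) >= 2 and abs(trace[-1] - trace[-2]) \
                    < self.tol * max(abs(trace[-2]), 1.0):
                converged = True
                break
        assert best is not None
        best.converged = converged
        if not converged:
            logger.info("MERF did not converge in %d iterations; best state kept",
                        self.max_iter)
        self.state_ = best
        return self

    # -- prediction ---------------------------------------------------------
    def predict_components(self, X: np.ndarray,
                           clusters: Optional[np.ndarray] = None):
        """(fixed-effect score, per-row intercept) before clipping."""
        if self.state_ is None:
            raise RuntimeError("model not fitted")
        fX = self.state_.forest.predict(np.asarray(X, dtype=float))
        if clusters is None:
            return fX, np.zeros_like(fX)
        b = np.array([self.state_.intercepts.get(c, 0.0) for c in np.asarray(clusters)])
        return fX, b

    def predict_score(self, X: np.ndarray,
                      clusters: Optional[np.ndarray] = None) -> np.ndarray:
        fX, b = self.predict_components(X, clusters)
        return np.clip(fX + b, 0.0, 1.0)

    def predict_label(self, X: np.ndarray, clusters: Optional[np.ndarray] = None,
                      threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(X, clusters) >= threshold).astype(int)
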