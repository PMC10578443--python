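"""Train/validation/test split plans for the four evaluation scenarios.

* ``random`` — stratified outer k-fold; the inner layer (model selection)
  runs its own k-fold inside the training pool.
* ``participant`` — leave-one-participant-out outer folds; the inner layer
  rotates a held-out participant as validation.
* ``temporal`` — per participant, the first 75% of observation days train,
  the next 12.5% validate, the final 12.5% test; one fixed fold, repeated
  with fresh sampling/model seeds.
* ``personalized`` — the temporal split applied within a single
  participant's data, one fold per participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

SCENARIOS = ("random", "participant", "temporal", "personalized")


@dataclass
class Fold:
    name: str
    train: np.ndarray
    test: np.ndarray
    validation: Optional[np.ndarray] = None   # None => inner CV on train
    test_participant: Optional[str] = None


@dataclass
class SplitPlan:
    scenario: str
    folds: List[Fold]
    seed: int
    n_repetitions: int = 1

    def check_disjoint(self) -> None:
        for f in self.folds:
            parts = [f.train, f.test] + ([f.validation] if f.validation is not None else [])
            allidx = np.concatenate(parts)
            if np.unique(allidx).size != allidx.size:
                raise AssertionError(f"fold {f.name}: overlapping arms")


def _day_rank(table: pd.DataFrame) -> pd.Series:
    """Ordinal rank of each row's observation day within its participant."""
    def rank(g: pd.Series) -> pd.Series:
        uniq = np.sort(g.unique())
        lookup = {d: i for i, d in enumerate(uniq)}
        return g.map(lookup)
    return table.groupby("participant")["day_index"].transform(rank)


def _temporal_arms(table: pd.DataFrame, participants: List[str]
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """75 / 12.5 / 12.5 day-quantile split, per participant, concatenated."""
    rank = _day_rank(table)
    n_days = table.groupby("participant")["day_index"].transform("nunique")
    tr, va, te = [], [], []
    for p in participants:
        m = table["participant"] == p
        d = int(n_days[m].iloc[0])
        cut1 = int(np.floor(0.75 * d))           # round down at the 75% boundary
        cut2 = int(np.ceil(0.875 * d))           # round up at the 87.5% boundary
        r = rank[m]
        idx = table.index[m]
        tr.append(idx[(r < cut1).to_numpy()])
        va.append(idx[((r >= cut1) & (r < cut2)).to_numpy()])
        te.append(idx[(r >= cut2).to_numpy()])
    return (np.concatenate(tr), np.concatenate(va), np.concatenate(te))


def make_split_plan(table: pd.DataFrame, scenario: str, seed: int = 0,
                    outer_k: int = 10, n_repetitions: int = 10,
                    min_days_personal: int = 8) -> SplitPlan:
    """Build a :class:`SplitPlan` for a feature table.

    The table needs ``label``, ``participant`` and ``day_index`` columns.
    The random scenario shrinks its outer fold count to the largest feasible
    k (logged) for small tables.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    table = table.reset_index(drop=True)
    y = (table["label"] == "event").astype(int).to_numpy()
    participants = sorted(table["participant"].unique())

    if scenario == "random":
        k = min(outer_k, int(np.bincount(y).min()))
        if k < 2:
            raise ValueError("random scenario needs >= 2 rows of each class")
        if k < outer_k:
            logger.info("random scenario: shrinking outer folds to k=%d", k)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [Fold(name=f"fold{i}", train=tr, test=te)
                 for i, (tr, te) in enumerate(skf.split(np.zeros_like(y), y))]
        return SplitPlan(scenario, folds, seed, n_repetitions=1)

    if scenario == "participant":
        if len(participants) < 3:
            raise ValueError("participant scenario needs >= 3 participants")
        folds = []
        for p in participants:
            te = np.flatnonzero((table["participant"] == p).to_numpy())
            tr = np.flatnonzero((table["participant"] != p).to_numpy())
            folds.append(Fold(name=f"loso_{p}", train=tr, test=te,
                              test_participant=p))
        return SplitPlan(scenario, folds, seed, n_repetitions=1)

    if scenario == "temporal":
        tr, va, te = _temporal_arms(table, participants)
        fold = Fold(name="temporal", train=tr, test=te, validation=va)
        return SplitPlan(scenario, [fold], seed, n_repetitions=n_repetitions)

    # personalized
    folds = []
    n_days = table.groupby("participant")["day_index"].nunique()
    for p in participants:
        if n_days[p] < min_days_personal:
            logger.info("personalized scenario: participant %s skipped "
                        "(%d < %d observation days)", p, n_days[p],
                        min_days_personal)
            continue
        sub = table[table["participant"] == p]
        tr, va, te = _temporal_arms(table.loc[sub.index], [p])
        folds.append(Fold(name=f"personal_{p}", train=tr, test=te,
                          validation=va, test_participant=p))
    if not folds:
        raise ValueError("no participant has enough observation days")
    return SplitPlan("personalized", folds, seed, n_repetitions=n_repetitions)
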