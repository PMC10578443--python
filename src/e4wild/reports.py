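"""Cohort acceptability summaries and in-lab rest-vs-exposure comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, extract_features
from .ingest import Session
from .windowing import LabeledWindow, segment_signals

logger = logging.getLogger(__name__)


def rest_vs_exposure_report(lab_sessions: Mapping[str, Mapping[str, Session]],
                            top_features: Sequence[str],
                            ) -> Dict[str, pd.DataFrame]:
    """Feature values under in-lab rest vs symptom-provocation conditions.

    ``lab_sessions`` maps participant -> {"rest": Session, "exposure":
    Session}; participants missing either condition are excluded (logged).
    Returns a long per-participant value table and a per-feature summary
    with condition medians and quartiles (box-plot statistics).
    """
    unknown = [f for f in top_features if f not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature(s): {unknown}")
    rows: List[dict] = []
    for pid, conds in sorted(lab_sessions.items()):
        if "rest" not in conds or "exposure" not in conds:
            logger.info("participant %s excluded from lab comparison "
                        "(missing condition)", pid)
            continue
        for cond in ("rest", "exposure"):
            s = conds[cond]
            start, end = s.span
            w = LabeledWindow(pid, s.session_id, start, min(end, start + 300.0),
                              "nonevent")
            feats = extract_features(segment_signals(w, s))
            for f in top_features:
                rows.append({"participant": pid, "condition": cond,
                             "feature": f, "value": feats[f]})
    values = pd.DataFrame(rows, columns=["participant", "condition",
                                         "feature", "value"])
    if values.empty:
        return {"values": values, "summary": pd.DataFrame()}
    summary = (values.groupby(["feature", "condition"])["value"]
               .quantile([0.25, 0.5, 0.75]).unstack()
               .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
               .reset_index())
    return {"values": values, "summary": summary}


@dataclass
class AcceptabilityReport:
    table: pd.DataFrame                    # per-participant descriptives
    totals: Dict[str, float]
    rho: Optional[pd.DataFrame]            # Spearman matrix (None if < 3 rows)
    p_values: Optional[pd.DataFrame]
    significant: Optional[pd.DataFrame]    # p < alpha flags


def acceptability_report(summary: pd.DataFrame,
                         metadata: Optional[pd.DataFrame] = None,
                         alpha: float = 0.01) -> AcceptabilityReport:
    """Cohort descriptives plus Spearman correlations among wear behavior,
    tagging behavior and participant metadata (age, symptom counts,
    severity).  Exact ties take average ranks; correlations are suppressed
    below three participants.
    """
    from .ingest import summarize_cohort_table

    table = summary.copy()
    if metadata is not None:
        table = table.join(metadata, how="left")
    totals = summarize_cohort_table(table)
    numeric = table.select_dtypes(include=[np.number]).dropna(axis=1, how="all")
    if len(table) < 3:
        logger.info("fewer than 3 participants; correlations suppressed")
        return AcceptabilityReport(table, totals, None, None, None)
    cols = numeric.columns
    k = len(cols)
    rho = np.ones((k, k))
    pv = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.spearmanr(numeric.iloc[:, i], numeric.iloc[:, j],
                                   nan_policy="omit")
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    pv_df = pd.DataFrame(pv, index=cols, columns=cols)
    sig = (pv_df < alpha) & ~np.eye(k, dtype=bool)
    return AcceptabilityReport(table, totals, rho_df, pv_df,
                               pd.DataFrame(sig, index=cols, columns=cols))
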