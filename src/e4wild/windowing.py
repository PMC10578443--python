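"""Event / buffer / nonevent windowing of tagged recordings.

Each surviving button press ``t`` defines an event window ``[t-300, t)``
(the five minutes leading up to the press) and a buffer ``[t, t+300)`` that
belongs to neither class.  Nonevent windows are drawn uniformly at random
from the remaining wear time.  A press whose event window would touch a
previous kept press's event window or buffer is dropped, which keeps all
emitted windows mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .ingest import CHANNEL_RATES, Session, WearMask, usable_tags

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowingParams:
    window_len: float = 300.0
    buffer_len: float = 300.0
    min_nonevents_per_session: int = 3
    #: cohort-wide negatives-per-positive target used above the per-session
    #: minimum (None = minimum only)
    nonevent_target_ratio: Optional[float] = 1.67
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be > 0")
        if self.buffer_len < 0:
            raise ValueError("buffer_len must be >= 0")
        if self.min_nonevents_per_session < 0:
            raise ValueError("min_nonevents_per_session must be >= 0")


@dataclass
class LabeledWindow:
    participant_id: str
    session_id: str
    start: float
    end: float
    label: str                      # "event" | "nonevent"
    source_tag: Optional[float] = None
    day_index: int = 0

    def as_interval(self) -> Tuple[float, float]:
        return (self.start, self.end)


@dataclass
class EventLabeling:
    events: List[LabeledWindow]
    buffers: List[Tuple[float, float]]
    dropped_tags: List[Tuple[float, str]] = field(default_factory=list)


class WindowRejected(ValueError):
    """A window cannot be segmented into complete channel slices."""


def label_events(session: Session, wear: Sequence[Tuple[float, float]],
                 params: WindowingParams = WindowingParams()) -> EventLabeling:
    """Turn tags into event windows and buffers.

    Tags are processed in time order.  A tag is kept only if (a) its event
    window lies wholly inside wear time and (b) the window clears the
    previous kept tag's buffer; otherwise it is dropped and logged.
    """
    W, B = params.window_len, params.buffer_len
    events: List[LabeledWindow] = []
    buffers: List[Tuple[float, float]] = []
    dropped: List[Tuple[float, str]] = []
    last_kept: Optional[float] = None
    for t in np.sort(np.asarray(session.tags, dtype=float)):
        if last_kept is not None and t - W < last_kept + B:
            dropped.append((t, "overlaps previous event/buffer"))
            continue
        if not iv.contains(wear, t - W, t):
            dropped.append((t, "event window not fully in wear time"))
            continue
        events.append(LabeledWindow(session.participant_id, session.session_id,
                                    t - W, t, "event", source_tag=t))
        buffers.append((t, t + B))
        last_kept = t
    for t, why in dropped:
        logger.info("session %s: tag %.0f dropped (%s)",
                    session.session_id, t, why)
    return EventLabeling(events=events, buffers=buffers, dropped_tags=dropped)


def sample_nonevents(session: Session, wear: Sequence[Tuple[float, float]],
                     labeling: EventLabeling,
                     params: WindowingParams = WindowingParams(),
                     count: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     ) -> List[LabeledWindow]:
    """Draw non-overlapping nonevent windows from the eligible wear time.

    Eligible time is wear minus event windows and buffers.  Starts are drawn
    uniformly over the whole-second grid; each placed window is removed from
    eligibility before the next draw.  If fewer than ``count`` windows fit,
    as many as fit are returned (logged).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if count is None:
        count = params.min_nonevents_per_session
    W = params.window_len
    exclusions = [w.as_interval() for w in labeling.events] + list(labeling.buffers)
    eligible = iv.subtract(wear, exclusions)
    out: List[LabeledWindow] = []
    for _ in range(count):
        grid: List[Tuple[int, int]] = []   # (first start, n starts) per interval
        counts = []
        for a, b in eligible:
            s0 = int(np.ceil(a))
            n = int(np.floor(b - W)) - s0 + 1
            if n > 0:
                grid.append((s0, n))
                counts.append(n)
        if not grid:
            break
        total = int(np.sum(counts))
        k = int(rng.integers(total))
        for (s0, n) in grid:
            if k < n:
                start = float(s0 + k)
                break
            k -= n
        out.append(LabeledWindow(session.participant_id, session.session_id,
                                 start, start + W, "nonevent"))
        eligible = iv.subtract(eligible, [(start, start + W)])
    if len(out) < count:
        logger.info("session %s: only %d of %d nonevents fit",
                    session.session_id, len(out), count)
    return out


def segment_signals(window: LabeledWindow, session: Session,
                    mask: Optional[WearMask] = None) -> Dict[str, np.ndarray]:
    """Per-channel slices for one window; raises :class:`WindowRejected`
    when any channel is incomplete or the window touches non-wear/sleep."""
    if mask is not None:
        bad = iv.normalize(mask.of_state("nonwear") + mask.of_state("sleep"))
        if iv.overlaps_any(bad, window.start, window.end):
            raise WindowRejected(
                f"window [{window.start}, {window.end}) intersects non-wear/sleep")
    slices: Dict[str, np.ndarray] = {}
    for name, rate in CHANNEL_RATES.items():
        ch = session.channels[name]
        try:
            x = ch.slice(window.start, window.end)
        except ValueError as exc:
            raise WindowRejected(str(exc)) from exc
        expected = int(round((window.end - window.start) * rate))
        if x.size != expected:
            raise WindowRejected(
                f"channel {name}: got {x.size} samples, expected {expected}")
        slices[name] = x
    return slices


def build_windows(sessions: Sequence[Session],
                  masks: Dict[Tuple[str, str], WearMask],
                  params: WindowingParams = WindowingParams()) -> pd.DataFrame:
    """Cohort-level windows table.

    Events and buffers are placed per session; the cohort nonevent budget is
    ``max(ratio x total events, 3 x n_sessions)`` apportioned over sessions
    by eligible-time share, with the per-session minimum enforced.
    ``day_index`` counts calendar days from each participant's first wear day.
    """
    rng = np.random.default_rng(params.seed)
    labelings: Dict[Tuple[str, str], EventLabeling] = {}
    eligible_time: Dict[Tuple[str, str], float] = {}
    wear_by_key: Dict[Tuple[str, str], List[Tuple[float, float]]] = {}
    total_events = 0
    for s in sessions:
        key = (s.participant_id, s.session_id)
        mask = masks[key]
        wear = mask.wear
        filtered = Session(s.participant_id, s.session_id, s.channels,
                           usable_tags(s, mask))
        lab = label_events(filtered, wear, params)
        labelings[key] = lab
        wear_by_key[key] = wear
        exclusions = [w.as_interval() for w in lab.events] + list(lab.buffers)
        eligible_time[key] = iv.total_duration(iv.subtract(wear, exclusions))
        total_events += len(lab.events)

    if params.nonevent_target_ratio is not None:
        target = int(round(params.nonevent_target_ratio * total_events))
    else:
        target = 0
    total_eligible = sum(eligible_time.values()) or 1.0

    rows: List[LabeledWindow] = []
    for s in sessions:
        key = (s.participant_id, s.session_id)
        share = int(round(target * eligible_time[key] / total_eligible))
        count = max(params.min_nonevents_per_session, share)
        nonevents = sample_nonevents(s, wear_by_key[key], labelings[key],
                                     params, count=count, rng=rng)
        rows.extend(labelings[key].events)
        rows.extend(nonevents)

    df = pd.DataFrame([{
        "participant": w.participant_id, "session": w.session_id,
        "start": w.start, "end": w.end, "label": w.label,
        "source_tag": w.source_tag,
    } for w in rows])
    if df.empty:
        return df.assign(day_index=pd.Series(dtype=int))
    day = (df["start"] // 86400).astype(int)
    first = day.groupby(df["participant"]).transform("min")
    df["day_index"] = (day - first).astype(int)
    return df.sort_values(["participant", "start"]).reset_index(drop=True)
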