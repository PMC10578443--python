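"""Reading, validating and wear-filtering E4-style biosensor sessions.

A session folder holds one single-column CSV per channel (``BVP.csv``,
``EDA.csv``, ``TEMP.csv``, ``HR.csv``) whose first row is the UTC start
timestamp in UNIX seconds, second row the sampling rate in Hz, and every
further row one sample; plus an optional ``tags.csv`` with one
event-button timestamp per row.

Wear filtering follows the usual wrist-sensor heuristics: sustained
near-zero skin conductance together with a skin temperature below body
range flags non-wear, and a recurring clock-time window flags sleep.
Sample ``i`` of a channel covers ``[start + i/rate, start + (i+1)/rate)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv

logger = logging.getLogger(__name__)

#: Required channels and their nominal sampling rates (Hz).
CHANNEL_RATES: Dict[str, float] = {"BVP": 64.0, "EDA": 4.0, "TEMP": 4.0, "HR": 1.0}

CHANNEL_FORMATS: Dict[str, str] = {"BVP": "%.6f", "EDA": "%.6f", "TEMP": "%.2f", "HR": "%.2f"}

SECONDS_PER_DAY = 86400


class SessionFormatError(ValueError):
    """Raised when a session folder violates the channel-file dialect."""


@dataclass
class ChannelSeries:
    """One uniformly sampled physiological channel."""

    name: str
    start_time: float
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.name not in CHANNEL_RATES:
            raise SessionFormatError(f"unknown channel name {self.name!r}")
        if self.values.size < 1:
            raise SessionFormatError(f"empty channel {self.name}")
        if not np.all(np.isfinite(self.values)):
            raise SessionFormatError(f"non-finite samples in channel {self.name}")
        if self.rate != CHANNEL_RATES[self.name]:
            logger.warning(
                "channel %s declares rate %g Hz (expected %g); accepting declared rate",
                self.name, self.rate, CHANNEL_RATES[self.name],
            )

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    def slice(self, start: float, end: float) -> np.ndarray:
        """Samples covering [start, end); boundaries must fall on the grid."""
        i0 = (start - self.start_time) * self.rate
        i1 = (end - self.start_time) * self.rate
        if abs(i0 - round(i0)) > 1e-6 or abs(i1 - round(i1)) > 1e-6:
            raise ValueError(f"window [{start}, {end}) not aligned to {self.name} grid")
        i0, i1 = int(round(i0)), int(round(i1))
        if i0 < 0 or i1 > self.values.size:
            raise ValueError(f"window [{start}, {end}) outside {self.name} coverage")
        return self.values[i0:i1]


@dataclass
class Session:
    """One continuous recording of all four channels plus event tags."""

    participant_id: str
    session_id: str
    channels: Dict[str, ChannelSeries]
    tags: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        missing = sorted(set(CHANNEL_RATES) - set(self.channels))
        if missing:
            raise SessionFormatError(f"missing required channel(s): {', '.join(missing)}")
        self.tags = np.asarray(self.tags, dtype=float)
        if self.tags.size and np.any(np.diff(self.tags) < 0):
            raise SessionFormatError("tags are not monotone non-decreasing")
        start, end = self.span
        keep = (self.tags >= start) & (self.tags <= end)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info(
                "session %s/%s: dropped %d tag(s) outside channel coverage",
                self.participant_id, self.session_id, n_drop,
            )
            self.tags = self.tags[keep]

    @property
    def span(self) -> Tuple[float, float]:
        starts = [c.start_time for c in self.channels.values()]
        ends = [c.end_time for c in self.channels.values()]
        return min(starts), max(ends)

    @property
    def duration(self) -> float:
        a, b = self.span
        return b - a


@dataclass
class WearMask:
    """Partition of a session span into wear / non-wear / sleep intervals."""

    intervals: List[Tuple[float, float, str]]

    STATES = ("wear", "nonwear", "sleep")

    def __post_init__(self) -> None:
        self.intervals = sorted(
            [(float(a), float(b), s) for a, b, s in self.intervals if b > a]
        )
        for (_, b0, _), (a1, _, _) in zip(self.intervals, self.intervals[1:]):
            if a1 < b0 - 1e-9:
                raise ValueError("wear-mask intervals overlap")
        for _, _, s in self.intervals:
            if s not in self.STATES:
                raise ValueError(f"unknown wear state {s!r}")

    def of_state(self, state: str) -> List[Tuple[float, float]]:
        return iv.normalize([(a, b) for a, b, s in self.intervals if s == state])

    @property
    def wear(self) -> List[Tuple[float, float]]:
        return self.of_state("wear")

    def durations(self) -> Dict[str, float]:
        out = {s: 0.0 for s in self.STATES}
        for a, b, s in self.intervals:
            out[s] += b - a
        return out

    @property
    def span(self) -> Tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]


# ---------------------------------------------------------------------------
# Folder I/O
# ---------------------------------------------------------------------------

def _read_channel_file(path: Path, name: str) -> ChannelSeries:
    if not path.exists():
        raise SessionFormatError(f"missing required channel file: {path}")
    raw = np.loadtxt(path, dtype=float, ndmin=1)
    if raw.size < 3:
        raise SessionFormatError(f"empty channel file (no samples): {path}")
    return ChannelSeries(name=name, start_time=float(raw[0]), rate=float(raw[1]),
                         values=raw[2:])


def read_session(folder: Path | str, participant_id: Optional[str] = None,
                 session_id: Optional[str] = None) -> Session:
    """Parse one session folder into a :class:`Session`.

    ``participant_id``/``session_id`` default to the folder name split on the
    first underscore (``P03_d01`` -> participant ``P03``, session ``P03_d01``).
    """
    folder = Path(folder)
    channels = {name: _read_channel_file(folder / f"{name}.csv", name)
                for name in CHANNEL_RATES}
    tags_path = folder / "tags.csv"
    if tags_path.exists() and tags_path.stat().st_size > 0:
        tags = np.loadtxt(tags_path, dtype=float, ndmin=1)
    else:
        tags = np.empty(0)
    name = folder.name
    pid = participant_id if participant_id is not None else name.split("_")[0]
    sid = session_id if session_id is not None else name
    return Session(participant_id=pid, session_id=sid, channels=channels, tags=tags)


def write_session(session: Session, folder: Path | str) -> Path:
    """Write a session back out in the same dialect :func:`read_session` reads."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    for name, ch in session.channels.items():
        fmt = CHANNEL_FORMATS[name]
        with open(folder / f"{name}.csv", "w") as fh:
            fh.write(f"{ch.start_time:.6f}\n{ch.rate:.6f}\n")
            np.savetxt(fh, ch.values, fmt=fmt)
    with open(folder / "tags.csv", "w") as fh:
        np.savetxt(fh, session.tags, fmt="%.2f")
    return folder


def sessions_to_table(sessions: Iterable[Session]) -> pd.DataFrame:
    """Long-format table of all samples: participant, session, channel, t, value."""
    frames = []
    for s in sessions:
        for name, ch in s.channels.items():
            frames.append(pd.DataFrame({
                "participant": s.participant_id, "session": s.session_id,
                "channel": name, "t": ch.times(), "value": ch.values,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Wear / sleep masking
# ---------------------------------------------------------------------------

def detect_nonwear(session: Session, eda_floor: float = 0.03,
                   temp_floor: float = 30.0, min_gap: float = 300.0) -> WearMask:
    """Flag sustained low-EDA + low-TEMP stretches as non-wear.

    A run of samples with ``EDA < eda_floor`` and ``TEMP < temp_floor``
    lasting at least ``min_gap`` seconds is classified non-wear; everything
    else in the session span is wear.
    """
    if min_gap <= 0:
        raise ValueError("min_gap must be > 0")
    eda = session.channels["EDA"]
    temp = session.channels["TEMP"]
    t = eda.times()
    temp_at = np.interp(t, temp.times(), temp.values)
    off = (eda.values < eda_floor) & (temp_at < temp_floor)

    nonwear: List[Tuple[float, float]] = []
    step = 1.0 / eda.rate
    idx = np.flatnonzero(np.diff(np.concatenate(([0], off.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        start, end = t[a], t[b - 1] + step
        if end - start >= min_gap:
            nonwear.append((start, end))
    span = session.span
    wear = iv.subtract([span], nonwear)
    parts = [(a, b, "nonwear") for a, b in nonwear] + [(a, b, "wear") for a, b in wear]
    return WearMask(parts)


def sleep_intervals(span: Tuple[float, float],
                    sleep_window: Tuple[float, float]) -> List[Tuple[float, float]]:
    """Daily recurring clock-time (UTC hours) sleep intervals clipped to span."""
    h0, h1 = sleep_window
    if not (0 <= h0 <= 24 and 0 <= h1 <= 24) or h0 == h1:
        raise ValueError(f"ill-formed sleep window {sleep_window!r}")
    a, b = span
    day0 = np.floor(a / SECONDS_PER_DAY) - 1
    out = []
    day = day0
    while day * SECONDS_PER_DAY < b:
        s = day * SECONDS_PER_DAY + h0 * 3600
        e = day * SECONDS_PER_DAY + h1 * 3600
        if h1 <= h0:  # wraps midnight
            e += SECONDS_PER_DAY
        out.append((s, e))
        day += 1
    return iv.intersect(out, [span])


def apply_sleep_mask(session: Session, sleep_window: Tuple[float, float] = (23.0, 7.0),
                     base: Optional[WearMask] = None) -> WearMask:
    """Overlay a recurring sleep window on a wear mask.

    Precedence sleep > non-wear > wear: sleep claims its clock interval
    regardless of the non-wear classification there.
    """
    if base is None:
        base = detect_nonwear(session)
    sleep = sleep_intervals(session.span, sleep_window)
    parts: List[Tuple[float, float, str]] = [(a, b, "sleep") for a, b in sleep]
    for state in ("nonwear", "wear"):
        for a, b in iv.subtract(base.of_state(state), sleep):
            parts.append((a, b, state))
    mask = WearMask(parts)
    durs = mask.durations()
    logger.info("session %s/%s: wear %.0f s, nonwear %.0f s, sleep %.0f s",
                session.participant_id, session.session_id,
                durs["wear"], durs["nonwear"], durs["sleep"])
    return mask


def usable_tags(session: Session, mask: WearMask) -> np.ndarray:
    """Tags inside wear time; tags in non-wear/sleep are dropped and counted."""
    wear = mask.wear
    keep = np.array([any(a <= t <= b for a, b in wear) for t in session.tags],
                    dtype=bool)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("session %s/%s: dropped %d tag(s) in non-wear/sleep",
                    session.participant_id, session.session_id, n_drop)
    return session.tags[keep]


# ---------------------------------------------------------------------------
# Wear summaries
# ---------------------------------------------------------------------------

def wear_summary(sessions: Sequence[Session],
                 masks: Optional[Mapping[Tuple[str, str], WearMask]] = None,
                 ) -> pd.DataFrame:
    """Per-participant wear/tag descriptives.

    Columns: n_tags, n_hours (wear only), n_days (calendar days with any
    wear), mean_hours_per_day, mean_tags_per_hour.  A participant with zero
    wear hours gets NaN tags-per-hour.
    """
    if not sessions:
        raise ValueError("need at least one session")
    rows: Dict[str, Dict[str, float]] = {}
    days: Dict[str, set] = {}
    for s in sessions:
        if masks is not None:
            mask = masks[(s.participant_id, s.session_id)]
        else:
            mask = WearMask([(s.span[0], s.span[1], "wear")])
        wear = mask.wear
        tags = usable_tags(s, mask)
        r = rows.setdefault(s.participant_id, {"n_tags": 0.0, "n_hours": 0.0})
        r["n_tags"] += tags.size
        r["n_hours"] += iv.total_duration(wear) / 3600.0
        dset = days.setdefault(s.participant_id, set())
        for a, b in wear:
            d = int(a // SECONDS_PER_DAY)
            while d * SECONDS_PER_DAY < b:
                dset.add(d)
                d += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant"
    df["n_days"] = [len(days[p]) for p in df.index]
    df["mean_hours_per_day"] = df["n_hours"] / df["n_days"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["mean_tags_per_hour"] = np.where(df["n_hours"] > 0,
                                            df["n_tags"] / df["n_hours"], np.nan)
    return df.sort_index()


def summarize_cohort_table(df: pd.DataFrame, n_enrolled: Optional[int] = None,
                           n_completed: Optional[int] = None) -> Dict[str, float]:
    """Cohort totals and unweighted means from a per-participant table.

    Expects columns ``n_tags``, ``n_hours``, ``n_days``,
    ``mean_hours_per_day``; ``retention_pct`` is added when enrollment
    counts are supplied (participants completing / enrolled).
    """
    out = {
        "total_tags": float(df["n_tags"].sum()),
        "total_hours": float(df["n_hours"].sum()),
        "total_days": float(df["n_days"].sum()),
        "mean_days": float(df["n_days"].mean()),
        "mean_hours_per_day": float(df["mean_hours_per_day"].mean()),
        "mean_tags": float(df["n_tags"].mean()),
    }
    if n_enrolled:
        out["retention_pct"] = 100.0 * (n_completed or 0) / n_enrolled
    return out
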