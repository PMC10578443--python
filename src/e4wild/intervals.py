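"""Half-open interval algebra on UNIX-second time axes.

All intervals are ``(start, end)`` with ``start < end``, half-open
``[start, end)``.  Lists are kept sorted and non-overlapping.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[float, float]


def normalize(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort, drop empties and merge touching/overlapping intervals."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    out: List[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def total_duration(intervals: Iterable[Interval]) -> float:
    return float(sum(b - a for a, b in intervals))


def intersect(xs: Iterable[Interval], ys: Iterable[Interval]) -> List[Interval]:
    xs, ys = normalize(xs), normalize(ys)
    out: List[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if b > a:
            out.append((a, b))
        if xs[i][1] <= ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(xs: Iterable[Interval], ys: Iterable[Interval]) -> List[Interval]:
    """Set difference xs \\ ys."""
    xs, ys = normalize(xs), normalize(ys)
    out: List[Interval] = []
    for a, b in xs:
        cur = a
        for c, d in ys:
            if d <= cur or c >= b:
                continue
            if c > cur:
                out.append((cur, c))
            cur = max(cur, d)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return out


def contains(intervals: Iterable[Interval], start: float, end: float) -> bool:
    """True if [start, end) lies wholly inside one interval of the list."""
    for a, b in normalize(intervals):
        if a <= start and end <= b:
            return True
    return False


def overlaps_any(intervals: Iterable[Interval], start: float, end: float) -> bool:
    for a, b in normalize(intervals):
        if max(a, start) < min(b, end):
            return True
    return False
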