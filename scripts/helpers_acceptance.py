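"""Minimal hand-built sessions and the brute-force windowing oracle used by
the acceptance script (independent of the library's windowing code)."""

import numpy as np

from e4wild import ChannelSeries, Session

T0 = 1_600_041_600 + 9 * 3600  # 09:00 UTC
W = B = 300.0


def make_session(duration=3600, tags=(), start=T0):
    n4 = duration * 4
    channels = {
        "BVP": ChannelSeries("BVP", start, 64.0, np.zeros(duration * 64) + 0.1),
        "EDA": ChannelSeries("EDA", start, 4.0, np.full(n4, 1.0)),
        "TEMP": ChannelSeries("TEMP", start, 4.0, np.full(n4, 33.0)),
        "HR": ChannelSeries("HR", start, 1.0, np.full(duration, 70.0)),
    }
    return Session("P00", "P00_s0", channels, np.asarray(tags, dtype=float))


def oracle_kept_tags(tags, wear):
    """Keep a tag iff its event window is wholly inside wear time and
    intersects no previously kept tag's event+buffer zone."""
    kept = []
    for t in sorted(tags):
        if not any(a <= t - W and t <= b for a, b in wear):
            continue
        if any(max(t - W, k - W) < min(t, k + B) for k in kept):
            continue
        kept.append(t)
    return kept
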