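"""Hand-built minimal sessions for unit tests."""

import numpy as np

from e4wild import ChannelSeries, Session

T0 = 1_600_041_600 + 9 * 3600  # 09:00 UTC on the generator's epoch day


def make_session(duration=1800, eda=None, temp=None, tags=(), start=T0):
    n4 = duration * 4
    channels = {
        "BVP": ChannelSeries("BVP", start, 64.0, np.zeros(duration * 64) + 0.1),
        "EDA": ChannelSeries("EDA", start, 4.0,
                             eda if eda is not None else np.full(n4, 1.0)),
        "TEMP": ChannelSeries("TEMP", start, 4.0,
                              temp if temp is not None else np.full(n4, 33.0)),
        "HR": ChannelSeries("HR", start, 1.0, np.full(duration, 70.0)),
    }
    return Session("P00", "P00_s0", channels, np.asarray(tags, dtype=float))
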